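"""Exception hierarchy for the endopatch pipeline."""


class EndopatchError(Exception):
    """Base class for all endopatch errors."""


class ParameterError(EndopatchError, ValueError):
    """Invalid parameter value."""


class DegenerateEventError(EndopatchError):
    """A simulated event would span fewer than two frames."""


class PlacementError(EndopatchError):
    """Events cannot be placed on the cell boundary at the requested
    minimum angular separation."""


class SegmentationError(EndopatchError):
    """No usable cell could be segmented from the frame."""


class GeometryError(EndopatchError):
    """A geometric construction (e.g. a kymograph ray) is undefined."""


class NoEventError(EndopatchError):
    """An intensity trace never exceeds the detection threshold."""


class NoOnsetError(EndopatchError):
    """A red trace contains no qualifying onset run."""


class NoT1Error(EndopatchError):
    """A green trace never sustainedly reaches the reference level."""


class UnclassifiableTrackError(EndopatchError):
    """A track is too short to classify."""


class UndefinedFractionError(EndopatchError):
    """A fraction with zero denominator was requested."""
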