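"""Group comparisons and cohort summaries.

The only hypothesis test used is the two-sided Mann-Whitney U test
(rank-sum), matching how lifetime and intensity cohorts are compared in this
kind of patch-dynamics study; no multiple-testing correction is applied
because comparisons are single pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .event_quant import PairedEvent, T1T2Result
from .patch_tracking import Track
from .synth_movie import CYTOPLASMIC_MOTILE, INTERNALIZING, STATIC


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) where U is the statistic of ``sample_a``. The p-value is
    exact (full enumeration of the U distribution) when the pooled size is at
    most 12 and there are no ties, otherwise the normal approximation with
    continuity correction and midrank tie handling is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) + len(b) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class CohortSummary:
    label: str
    n: int
    lifetime_mean_s: float = float("nan")
    lifetime_sd_s: float = float("nan")
    max_intensity_mean: float = float("nan")
    max_intensity_sd: float = float("nan")
    onset_fraction_mean: float = float("nan")
    onset_fraction_sd: float = float("nan")
    t1t2: T1T2Result | None = None
    n_static: int = 0
    n_internalizing: int = 0
    n_motile: int = 0
    arrival_delay_mean_s: float = float("nan")
    arrival_delay_sd_s: float = float("nan")

    @property
    def static_percent(self) -> float:
        tot = self.n_static + self.n_internalizing + self.n_motile
        return round(100.0 * self.n_static / tot, 1) if tot else float("nan")

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "n": self.n,
            "lifetime_mean_s": self.lifetime_mean_s,
            "lifetime_sd_s": self.lifetime_sd_s,
            "max_intensity_mean": self.max_intensity_mean,
            "max_intensity_sd": self.max_intensity_sd,
            "onset_fraction_mean": self.onset_fraction_mean,
            "onset_fraction_sd": self.onset_fraction_sd,
            "n_static": self.n_static,
            "n_internalizing": self.n_internalizing,
            "n_motile": self.n_motile,
            "static_percent": self.static_percent,
            "arrival_delay_mean_s": self.arrival_delay_mean_s,
            "arrival_delay_sd_s": self.arrival_delay_sd_s,
        }
        if self.t1t2 is not None:
            d["t1t2"] = {
                "slope": self.t1t2.slope,
                "intercept_s": self.t1t2.intercept_s,
                "r_squared": self.t1t2.r_squared,
                "n_events": self.t1t2.n_events,
                "reference_level": self.t1t2.reference_level,
            }
        return d


def _mean_sd(values) -> tuple[float, float]:
    v = np.asarray([x for x in values if x is not None and np.isfinite(x)])
    if len(v) == 0:
        return float("nan"), float("nan")
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0


def summarize_cohort(lifetimes_s: list[float],
                     max_intensities: list[float],
                     tracks: list[Track],
                     pairs: list[PairedEvent] | None = None,
                     t1t2: T1T2Result | None = None,
                     label: str = "cohort") -> CohortSummary:
    """Aggregate per-event measurements into one cohort summary; tracks with
    the crowded-exclusion flag are not counted."""
    tracks = [t for t in tracks if not t.excluded_crowded]
    lm, ls = _mean_sd(lifetimes_s)
    im, isd = _mean_sd(max_intensities)
    summary = CohortSummary(
        label=label, n=len(lifetimes_s),
        lifetime_mean_s=lm, lifetime_sd_s=ls,
        max_intensity_mean=im, max_intensity_sd=isd,
        n_static=sum(t.motility_class == STATIC for t in tracks),
        n_internalizing=sum(t.motility_class == INTERNALIZING for t in tracks),
        n_motile=sum(t.motility_class == CYTOPLASMIC_MOTILE for t in tracks),
        t1t2=t1t2,
    )
    if pairs:
        fm, fs = _mean_sd([p.onset_fraction for p in pairs])
        summary.onset_fraction_mean, summary.onset_fraction_sd = fm, fs
        dm, ds = _mean_sd([p.arrival_delay_s for p in pairs])
        summary.arrival_delay_mean_s, summary.arrival_delay_sd_s = dm, ds
    return summary
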