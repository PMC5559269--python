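"""Synthetic two-channel cortical-patch movie generator.

Emulates single budding-yeast cells imaged by wide-field fluorescence at
65 nm/pixel: diffraction-limited cortical patches whose green-channel
(nucleation-promoting factor, e.g. Las17/Vrp1/Sla1) intensity ramps up to a
maximum over tens of seconds, a red channel (actin marker, e.g. Abp1/Sac6)
whose onset is coupled to the green trace crossing a fixed fraction of its
maximum, late inward internalization movement, and an alternative
"comet-tail" condition with static green cortical patches plus independently
moving red objects trailing decaying intensity.

Every event carries full ground truth (onset/offset frames, red onset,
trajectory, motility class) so downstream detection, tracking and event
statistics can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateEventError, ParameterError, PlacementError

GREEN, RED = 0, 1
CHANNEL_NAMES = ("green", "red")

STATIC = "static"
INTERNALIZING = "internalizing"
CYTOPLASMIC_MOTILE = "cytoplasmic_motile"


@dataclass
class SimParams:
    """Parameters of the synthetic imaging experiment.

    Defaults describe the wild-type condition: a ~3.5 um diameter cell at
    65 nm/pixel, 1 frame/s, Sla1-like patch lifetimes (24.1 +/- 4.9 s), and
    actin onset fired when the green trace first crosses 75% of its maximum.
    Intensities are in arbitrary photon-scaled units (no camera calibration).
    """

    cell_radius_px: float = 27.0
    pixel_size_nm: float = 65.0
    frame_interval_s: float = 1.0
    n_frames: int = 150
    n_events: int = 8
    lifetime_mean_s: float = 24.1
    lifetime_sd_s: float = 4.9
    lifetime_min_s: float = 4.0
    rise_fraction: float = 0.6
    peak_amplitude_photons: float = 2000.0
    amplitude_cv: float = 0.1
    threshold_fraction_f: float = 0.75
    #: if set, the per-event coupling fraction is drawn uniformly in this range
    threshold_fraction_range: tuple[float, float] | None = None
    red_rise_s: float = 6.0
    red_amplitude_photons: float = 1500.0
    #: "threshold": red fires at the green fraction-of-max crossing;
    #: "delay": red fires a normally distributed time after green onset
    onset_mode: str = "threshold"
    onset_delay_mean_s: float = 12.6
    onset_delay_sd_s: float = 4.9
    internalization_depth_px: float = 3.0
    static_fraction: float = 0.0
    drift_speed_px_per_frame: float = 0.15
    comet_mode: bool = False
    comet_speed_px_per_frame: float = 0.5
    n_comets: int = 4
    comet_tail_decay_s: float = 4.0
    psf_sigma_px: float = 1.5
    background_photons: float = 20.0
    cell_fill_photons: float = 12.0
    read_noise_sd: float = 2.0
    apply_noise: bool = True
    min_angular_separation_rad: float = 0.5
    frame_size_px: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.frame_interval_s, self.lifetime_mean_s, self.lifetime_min_s) <= 0:
            raise ParameterError("all times must be positive")
        if not (0.0 < self.threshold_fraction_f <= 1.0):
            raise ParameterError("threshold_fraction_f must be in (0, 1]")
        if self.threshold_fraction_range is not None:
            lo, hi = self.threshold_fraction_range
            if not (0.0 < lo <= hi <= 1.0):
                raise ParameterError("threshold_fraction_range must lie in (0, 1]")
        if not (0.0 <= self.static_fraction <= 1.0):
            raise ParameterError("static_fraction must be in [0, 1]")
        if self.min_angular_separation_rad <= 0:
            raise ParameterError("min_angular_separation_rad must be positive")
        if not (0.0 < self.rise_fraction <= 1.0):
            raise ParameterError("rise_fraction must be in (0, 1]")
        if self.cell_radius_px <= 0 or self.psf_sigma_px <= 0:
            raise ParameterError("lengths must be positive")
        if self.n_frames < 1 or self.n_events < 0:
            raise ParameterError("counts must be non-negative (n_frames >= 1)")

    @property
    def shape(self) -> tuple[int, int]:
        if self.frame_size_px is not None:
            return (self.frame_size_px, self.frame_size_px)
        side = int(2 * math.ceil(self.cell_radius_px + 14))
        return (side, side)

    @property
    def center(self) -> tuple[float, float]:
        h, w = self.shape
        return ((h - 1) / 2.0, (w - 1) / 2.0)


@dataclass
class GroundTruthEvent:
    """Ground truth for one simulated patch (or comet) event.

    Frames are absolute movie frames; ``trajectory`` has one (row, col) per
    frame of the green (or red, for comets) support, onset..offset inclusive.
    """

    event_id: int
    channel: str
    onset_frame: int
    offset_frame: int
    red_onset_frame: int | None
    red_offset_frame: int | None
    true_lifetime_s: float
    true_lifetime_red_s: float | None
    site_angle_rad: float
    true_threshold_fraction: float | None
    motility_class: str
    amplitude: float
    trajectory: np.ndarray  # (n_frames_alive, 2) rows of (row, col)

    def __post_init__(self) -> None:
        if self.offset_frame < self.onset_frame:
            raise ValueError("onset must not exceed offset")
        if len(self.trajectory) != self.offset_frame - self.onset_frame + 1:
            raise ValueError("trajectory length must equal offset - onset + 1")


@dataclass
class Movie:
    """Two-channel image stack, dimension order [frame, channel, row, col]."""

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("movie data must be 4-D [frame, channel, row, col]")
        if self.data.shape[0] < 1:
            raise ValueError("movie must have at least one frame")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    def channel(self, name_or_index: int | str) -> np.ndarray:
        if isinstance(name_or_index, str):
            name_or_index = self.channel_names.index(name_or_index)
        return self.data[:, name_or_index]


# ---------------------------------------------------------------------------
# per-event traces


def _event_rng(params: SimParams, event_seed: int) -> np.random.Generator:
    # per-event sub-stream keyed by (root seed, event index): event k is
    # reproducible regardless of how many other events are drawn
    return np.random.default_rng(np.random.SeedSequence([params.seed, event_seed]))


def _draw_lifetime_frames(params: SimParams, rng: np.random.Generator,
                          max_s: float | None = None) -> int:
    """Normal lifetime draw truncated below at lifetime_min_s (and above at
    max_s when the movie must contain the whole event)."""
    for _ in range(1000):
        life_s = rng.normal(params.lifetime_mean_s, params.lifetime_sd_s)
        if life_s < params.lifetime_min_s:
            continue
        if max_s is not None and life_s > max_s:
            continue
        n = int(round(life_s / params.frame_interval_s))
        if n >= 2:
            return n
    raise DegenerateEventError("could not draw a lifetime of at least 2 frames")


def _green_profile(n_life: int, amplitude: float, rise_fraction: float,
                   with_decline: bool) -> np.ndarray:
    """Piecewise-linear rise to max, plateau, then (for internalizing events)
    a linear decline over the final quarter of the lifetime."""
    n_rise = max(1, int(round(rise_fraction * n_life)))
    n_rise = min(n_rise, n_life)
    n_decl = min(n_life - n_rise, max(1, n_life // 4)) if with_decline else 0
    g = np.empty(n_life, dtype=float)
    for i in range(n_life):
        if i < n_rise:
            g[i] = amplitude * (i + 1) / n_rise
        elif i >= n_life - n_decl:
            j = i - (n_life - n_decl) + 1
            g[i] = amplitude * (1.0 - j / (n_decl + 1.0))
        else:
            g[i] = amplitude
    return g


def simulate_event_trace(
    params: SimParams, event_seed: int, *, max_lifetime_s: float | None = None
) -> tuple[np.ndarray, np.ndarray, GroundTruthEvent]:
    """Noiseless green/red intensity traces and ground truth for one event.

    The green trace rises monotonically to its maximum over
    ``rise_fraction * lifetime`` and declines during internalization. The red
    trace is zero until the first frame where the noiseless green trace is at
    least ``f * max(green)`` (threshold mode) or until a drawn onset delay has
    elapsed (delay mode), then rises over ``red_rise_s``.

    Frames in the returned truth are event-local (onset_frame = 0);
    :func:`simulate_movie` shifts them to absolute movie frames.
    """
    rng = _event_rng(params, event_seed)
    n_life = _draw_lifetime_frames(params, rng, max_s=max_lifetime_s)
    amp = params.peak_amplitude_photons * max(
        0.2, rng.normal(1.0, params.amplitude_cv)
    )
    green = _green_profile(n_life, amp, params.rise_fraction, with_decline=True)

    if params.onset_mode == "threshold":
        if params.threshold_fraction_range is not None:
            lo, hi = params.threshold_fraction_range
            f = float(rng.uniform(lo, hi))
        else:
            f = params.threshold_fraction_f
        onset = int(np.argmax(green >= f * green.max() - 1e-12))
    elif params.onset_mode == "delay":
        f = None
        delay_s = -1.0
        hi = (n_life - 2) * params.frame_interval_s
        while not (0.0 <= delay_s <= hi):
            delay_s = rng.normal(params.onset_delay_mean_s, params.onset_delay_sd_s)
        onset = int(round(delay_s / params.frame_interval_s))
    else:
        raise ParameterError(f"unknown onset_mode {params.onset_mode!r}")

    n_red_rise = max(1, int(round(params.red_rise_s / params.frame_interval_s)))
    red = np.zeros(n_life)
    for i in range(onset, n_life):
        red[i] = params.red_amplitude_photons * min(1.0, (i - onset + 1) / n_red_rise)
    # dim with the green decline (vesicle leaving the imaging plane)
    scale = np.clip(green / green.max(), 0.0, 1.0)
    decl_start = int(np.argmax(green == green.max()))
    red[decl_start:] *= scale[decl_start:]

    truth = GroundTruthEvent(
        event_id=event_seed,
        channel="green",
        onset_frame=0,
        offset_frame=n_life - 1,
        red_onset_frame=onset,
        red_offset_frame=n_life - 1,
        true_lifetime_s=n_life * params.frame_interval_s,
        true_lifetime_red_s=(n_life - onset) * params.frame_interval_s,
        site_angle_rad=float("nan"),
        true_threshold_fraction=f,
        motility_class=INTERNALIZING,
        amplitude=amp,
        trajectory=np.zeros((n_life, 2)),
    )
    return green, red, truth


# ---------------------------------------------------------------------------
# geometry helpers


def _n_static(n_events: int, static_fraction: float) -> int:
    # nearest count, ties toward static (round half up)
    return min(n_events, int(math.floor(static_fraction * n_events + 0.5)))


def _place_angles(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n_events
    sep = params.min_angular_separation_rad
    if n == 0:
        return np.empty(0)
    if n * sep > 2 * math.pi:
        raise PlacementError(
            f"{n} events cannot satisfy angular separation {sep:.3f} rad"
        )
    if n == 1:
        return rng.uniform(0, 2 * math.pi, size=1)
    # uniform angles conditioned on all circular gaps >= sep: spread the
    # slack 2*pi - n*sep uniformly (sorted uniforms), add the minimum gaps,
    # then rotate and shuffle
    slack = 2 * math.pi - n * sep
    u = np.sort(rng.uniform(0, slack, size=n))
    angles = u + sep * np.arange(n) + rng.uniform(0, 2 * math.pi)
    angles = np.mod(angles, 2 * math.pi)
    rng.shuffle(angles)
    gaps = np.diff(np.concatenate([np.sort(angles),
                                   [np.sort(angles)[0] + 2 * math.pi]]))
    if gaps.min() < sep - 1e-9:
        raise PlacementError("could not satisfy angular separation")
    return angles


def _angle_to_pos(center: tuple[float, float], radius: float, theta: float
                  ) -> tuple[float, float]:
    # x = col, y = row; theta measured from +col axis
    return (center[0] + radius * math.sin(theta), center[1] + radius * math.cos(theta))


def _render_gaussian(img: np.ndarray, row: float, col: float, amp: float,
                     sigma: float) -> None:
    if amp <= 0:
        return
    h, w = img.shape
    half = int(math.ceil(5 * sigma))
    r0, r1 = int(math.floor(row)) - half, int(math.floor(row)) + half + 1
    c0, c1 = int(math.floor(col)) - half, int(math.floor(col)) + half + 1
    r0, r1 = max(0, r0), min(h, r1)
    c0, c1 = max(0, c0), min(w, c1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    norm = amp / (2 * math.pi * sigma**2)
    img[r0:r1, c0:c1] += norm * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def _base_frame(params: SimParams) -> np.ndarray:
    """Uniform camera/media background plus a soft-edged cytoplasmic fill."""
    h, w = params.shape
    base = np.full((h, w), params.background_photons, dtype=float)
    if params.cell_fill_photons > 0:
        cy, cx = params.center
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.hypot(yy - cy, xx - cx)
        # logistic edge of ~2 px width: soft like a real cell outline
        base += params.cell_fill_photons / (1 + np.exp((d - params.cell_radius_px) / 1.5))
    return base


def _apply_noise(data: np.ndarray, params: SimParams,
                 rng: np.random.Generator) -> np.ndarray:
    if not params.apply_noise:
        return data
    noisy = rng.poisson(np.clip(data, 0, None)).astype(float)
    noisy += rng.normal(0.0, params.read_noise_sd, size=data.shape)
    return np.clip(noisy, 0, None)


# ---------------------------------------------------------------------------
# movies


def _event_trajectory(params: SimParams, theta: float, n_life: int,
                      motility: str, direction: float = 1.0) -> np.ndarray:
    center = params.center
    radius = params.cell_radius_px
    traj = np.empty((n_life, 2))
    if motility == STATIC:
        traj[:] = _angle_to_pos(center, radius, theta)
    elif motility == INTERNALIZING:
        q = max(1, n_life // 4)
        for i in range(n_life):
            into = max(0, i - (n_life - q - 1))
            r = radius - params.internalization_depth_px * into / q
            traj[i] = _angle_to_pos(center, r, theta)
    elif motility == CYTOPLASMIC_MOTILE:
        # slow tangential drift along the cortex
        omega = direction * params.drift_speed_px_per_frame / radius
        for i in range(n_life):
            traj[i] = _angle_to_pos(center, radius, theta + omega * i)
    else:
        raise ParameterError(f"unknown motility class {motility!r}")
    return traj


def simulate_movie(params: SimParams) -> tuple[Movie, list[GroundTruthEvent]]:
    """Render a wild-type-like movie: cortical events, red onset coupled to
    the green trace, internalization of the non-static fraction, Poisson shot
    noise on (signal + background) plus additive Gaussian read noise."""
    rng_layout = np.random.default_rng(np.random.SeedSequence([params.seed, 1_000_003]))
    angles = _place_angles(params, rng_layout)
    n_static = _n_static(params.n_events, params.static_fraction)

    h, w = params.shape
    data = np.empty((params.n_frames, 2, h, w))
    base = _base_frame(params)
    data[:, :] = base

    max_life_s = (params.n_frames - 6) * params.frame_interval_s
    truths: list[GroundTruthEvent] = []
    for k in range(params.n_events):
        green, red, truth = simulate_event_trace(params, k, max_lifetime_s=max_life_s)
        n_life = len(green)
        start = int(rng_layout.integers(2, max(3, params.n_frames - n_life - 2)))
        motility = STATIC if k < n_static else INTERNALIZING
        traj = _event_trajectory(params, angles[k], n_life, motility)
        for i in range(n_life):
            t = start + i
            _render_gaussian(data[t, GREEN], traj[i, 0], traj[i, 1], green[i],
                             params.psf_sigma_px)
            _render_gaussian(data[t, RED], traj[i, 0], traj[i, 1], red[i],
                             params.psf_sigma_px)
        truths.append(
            GroundTruthEvent(
                event_id=k,
                channel="green",
                onset_frame=start,
                offset_frame=start + n_life - 1,
                red_onset_frame=(start + truth.red_onset_frame
                                 if truth.red_onset_frame is not None else None),
                red_offset_frame=start + n_life - 1,
                true_lifetime_s=n_life * params.frame_interval_s,
                true_lifetime_red_s=truth.true_lifetime_red_s,
                site_angle_rad=float(angles[k]),
                true_threshold_fraction=truth.true_threshold_fraction,
                motility_class=motility,
                amplitude=truth.amplitude,
                trajectory=traj,
            )
        )

    rng_noise = np.random.default_rng(np.random.SeedSequence([params.seed, 999_983]))
    data = _apply_noise(data, params, rng_noise)
    movie = Movie(data, params.pixel_size_nm, params.frame_interval_s)
    return movie, truths


def simulate_comet_condition(params: SimParams) -> tuple[Movie, list[GroundTruthEvent]]:
    """Double-mutant-like condition: green cortical patches that are static
    (fraction ``static_fraction``, nearest-count rounding, ties toward static)
    or slowly drifting, and red comet objects moving independently with a
    leading punctum plus an exponentially decaying trailing intensity."""
    if not params.comet_mode:
        raise ParameterError("simulate_comet_condition requires comet_mode=True")
    if params.comet_speed_px_per_frame <= 0:
        raise ParameterError("comet_speed_px_per_frame must be positive")

    rng_layout = np.random.default_rng(np.random.SeedSequence([params.seed, 1_000_003]))
    angles = _place_angles(params, rng_layout)
    n_static = _n_static(params.n_events, params.static_fraction)

    h, w = params.shape
    data = np.empty((params.n_frames, 2, h, w))
    data[:, :] = _base_frame(params)

    max_life_s = (params.n_frames - 6) * params.frame_interval_s
    truths: list[GroundTruthEvent] = []
    for k in range(params.n_events):
        rng = _event_rng(params, k)
        n_life = _draw_lifetime_frames(params, rng, max_s=max_life_s)
        amp = params.peak_amplitude_photons * max(0.2, rng.normal(1.0, params.amplitude_cv))
        green = _green_profile(n_life, amp, params.rise_fraction, with_decline=False)
        start = int(rng_layout.integers(2, max(3, params.n_frames - n_life - 2)))
        motility = STATIC if k < n_static else CYTOPLASMIC_MOTILE
        direction = 1.0 if rng_layout.uniform() < 0.5 else -1.0
        traj = _event_trajectory(params, angles[k], n_life, motility, direction)
        for i in range(n_life):
            _render_gaussian(data[start + i, GREEN], traj[i, 0], traj[i, 1],
                             green[i], params.psf_sigma_px)
        truths.append(
            GroundTruthEvent(
                event_id=k,
                channel="green",
                onset_frame=start,
                offset_frame=start + n_life - 1,
                red_onset_frame=None,
                red_offset_frame=None,
                true_lifetime_s=n_life * params.frame_interval_s,
                true_lifetime_red_s=None,
                site_angle_rad=float(angles[k]),
                true_threshold_fraction=None,
                motility_class=motility,
                amplitude=amp,
                trajectory=traj,
            )
        )

    # red comets: straight-line motion through the cytoplasm, reflected off a
    # ring at 0.9 R; the trail decays exponentially along the recent trajectory
    tau = params.comet_tail_decay_s / params.frame_interval_s
    n_tail = int(math.ceil(3 * tau))
    cy, cx = params.center
    rmax = 0.9 * params.cell_radius_px
    for c in range(params.n_comets):
        rng = _event_rng(params, 10_000 + c)
        r0 = rng.uniform(0.1, 0.6) * params.cell_radius_px
        th0 = rng.uniform(0, 2 * math.pi)
        pos = np.array(_angle_to_pos((cy, cx), r0, th0))
        phi = rng.uniform(0, 2 * math.pi)
        vel = params.comet_speed_px_per_frame * np.array([math.sin(phi), math.cos(phi)])
        traj = np.empty((params.n_frames, 2))
        for t in range(params.n_frames):
            traj[t] = pos
            nxt = pos + vel
            if np.hypot(nxt[0] - cy, nxt[1] - cx) > rmax:
                radial = (pos - (cy, cx)) / max(1e-9, np.hypot(pos[0] - cy, pos[1] - cx))
                vel = vel - 2 * np.dot(vel, radial) * radial
                nxt = pos + vel
            pos = nxt
        for t in range(params.n_frames):
            for k_back in range(0, min(n_tail, t) + 1):
                amp_t = params.red_amplitude_photons * math.exp(-k_back / tau)
                p = traj[t - k_back]
                _render_gaussian(data[t, RED], p[0], p[1], amp_t, params.psf_sigma_px)
        truths.append(
            GroundTruthEvent(
                event_id=params.n_events + c,
                channel="red",
                onset_frame=0,
                offset_frame=params.n_frames - 1,
                red_onset_frame=0,
                red_offset_frame=params.n_frames - 1,
                true_lifetime_s=params.n_frames * params.frame_interval_s,
                true_lifetime_red_s=params.n_frames * params.frame_interval_s,
                site_angle_rad=float(th0),
                true_threshold_fraction=None,
                motility_class=CYTOPLASMIC_MOTILE,
                amplitude=params.red_amplitude_photons,
                trajectory=traj,
            )
        )

    rng_noise = np.random.default_rng(np.random.SeedSequence([params.seed, 999_983]))
    data = _apply_noise(data, params, rng_noise)
    movie = Movie(data, params.pixel_size_nm, params.frame_interval_s)
    return movie, truths
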