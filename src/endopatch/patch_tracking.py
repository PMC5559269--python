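"""Spot detection, frame-to-frame linking, motility classification and the
crowded-patch exclusion rule.

Cortical endocytic patches are diffraction-limited; detection is a
difference-of-Gaussians band-pass followed by local-maximum picking against a
robust noise estimate, with subpixel localization by intensity-weighted
centroid. Linking is optimal bipartite assignment per frame pair with gap
closing under a constant-position prediction (patch speeds are sub-pixel per
frame, so no motion model is used). Patches that are ever too close to
another patch to be clearly resolved are excluded from quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .cell_geometry import CellOutline, signed_boundary_distance
from .errors import UnclassifiableTrackError
from .synth_movie import CYTOPLASMIC_MOTILE, INTERNALIZING, STATIC


@dataclass
class DetectionParams:
    sigma_spot: float = 1.5         # px, diffraction-limited blob at 65 nm/px
    k_det: float = 4.0              # robust SDs above background in the DoG image
    min_distance_px: int = 3
    aperture_radius_px: float = 3.0
    annulus_px: tuple[float, float] = (5.0, 8.0)


@dataclass
class LinkParams:
    max_link_dist_px: float = 3.0
    gap_max: int = 2
    min_track_len: int = 4


@dataclass
class MotilityThresholds:
    static_max_net_disp_px: float = 2.0
    inward_min_disp_px: float = 2.0
    cortex_band_px: float = 3.0


@dataclass
class Spot:
    frame: int
    channel: str
    position: tuple[float, float]   # (row, col), subpixel
    raw_intensity: float            # aperture sum minus local background
    local_background: float         # per-pixel background estimate


@dataclass
class Track:
    track_id: int
    channel: str
    spots: list[Spot]
    motility_class: str | None = None
    excluded_crowded: bool = False

    @property
    def birth_frame(self) -> int:
        return self.spots[0].frame

    @property
    def death_frame(self) -> int:
        return self.spots[-1].frame

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def frames(self) -> np.ndarray:
        return np.array([s.frame for s in self.spots])

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.spots])

    def position_at(self, frame: int) -> np.ndarray:
        """Position at an arbitrary movie frame: linear interpolation inside
        the track span, nearest endpoint outside it."""
        f = self.frames()
        p = self.positions()
        frame = np.clip(frame, f[0], f[-1])
        r = np.interp(frame, f, p[:, 0])
        c = np.interp(frame, f, p[:, 1])
        return np.array([r, c])


# ---------------------------------------------------------------------------
# detection


def _robust_sd(img: np.ndarray) -> float:
    med = np.median(img)
    return 1.4826 * float(np.median(np.abs(img - med)))


def aperture_photometry(frame: np.ndarray, position: tuple[float, float],
                        aperture_radius_px: float,
                        annulus_px: tuple[float, float]) -> tuple[float, float, bool]:
    """Background-corrected aperture sum at ``position``.

    Returns (net intensity, per-pixel background, clipped) where clipped
    flags an aperture truncated by the frame edge.
    """
    h, w = frame.shape
    r0, c0 = position
    rad = aperture_radius_px
    rin, rout = annulus_px
    lo_r, hi_r = int(math.floor(r0 - rout)), int(math.ceil(r0 + rout)) + 1
    lo_c, hi_c = int(math.floor(c0 - rout)), int(math.ceil(c0 + rout)) + 1
    # clipped means the aperture disc itself crosses the frame edge
    clipped = (r0 - rad < -0.5 or c0 - rad < -0.5
               or r0 + rad > h - 0.5 or c0 + rad > w - 0.5)
    lo_r, hi_r = max(0, lo_r), min(h, hi_r)
    lo_c, hi_c = max(0, lo_c), min(w, hi_c)
    yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    d = np.hypot(yy - r0, xx - c0)
    ap = d <= rad
    an = (d >= rin) & (d <= rout)
    sub = frame[lo_r:hi_r, lo_c:hi_c]
    bg = float(np.median(sub[an])) if an.any() else 0.0
    n_ap = int(ap.sum())
    net = float(sub[ap].sum() - bg * n_ap)
    return net, bg, clipped


def detect_spots(frame: np.ndarray, channel: str,
                 params: DetectionParams | None = None) -> list[Spot]:
    """Detect diffraction-limited spots in one frame.

    Band-pass by difference of Gaussians at (sigma, 2*sigma), keep local
    maxima exceeding k_det robust SDs of the band-passed image, localize by
    intensity-weighted centroid in a 5x5 window.
    """
    params = params or DetectionParams()
    frame = np.asarray(frame, dtype=float)
    dog = (ndimage.gaussian_filter(frame, params.sigma_spot)
           - ndimage.gaussian_filter(frame, 2 * params.sigma_spot))
    sd = _robust_sd(dog)
    thr = params.k_det * sd
    if thr <= 0:
        thr = np.inf  # perfectly flat frame: nothing to detect
    size = 2 * params.min_distance_px + 1
    is_max = dog == ndimage.maximum_filter(dog, size=size)
    cand = np.argwhere(is_max & (dog > np.median(dog) + thr))

    spots: list[Spot] = []
    h, w = frame.shape
    for r, c in cand:
        lo_r, hi_r = max(0, r - 2), min(h, r + 3)
        lo_c, hi_c = max(0, c - 2), min(w, c + 3)
        win = dog[lo_r:hi_r, lo_c:hi_c]
        win = np.clip(win - win.min(), 0, None)
        tot = win.sum()
        if tot <= 0:
            pos = (float(r), float(c))
        else:
            yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
            pos = (float((win * yy).sum() / tot), float((win * xx).sum() / tot))
        net, bg, _ = aperture_photometry(frame, pos, params.aperture_radius_px,
                                         params.annulus_px)
        spots.append(Spot(frame=-1, channel=channel, position=pos,
                          raw_intensity=max(net, 0.0), local_background=bg))
    spots.sort(key=lambda s: s.position)
    return spots


def detect_movie(channel_stack: np.ndarray, channel: str,
                 params: DetectionParams | None = None) -> list[list[Spot]]:
    """Detect spots on every frame of a single-channel stack."""
    out = []
    for t, frame in enumerate(channel_stack):
        spots = detect_spots(frame, channel, params)
        for s in spots:
            s.frame = t
        out.append(spots)
    return out


# ---------------------------------------------------------------------------
# linking


def link_tracks(spots_by_frame: list[list[Spot]],
                params: LinkParams | None = None) -> list[Track]:
    """Link per-frame detections into tracks.

    Per frame, open track ends (within gap_max frames) are assigned to
    detections by optimal bipartite assignment on Euclidean distance; links
    longer than max_link_dist_px are forbidden. Tracks shorter than
    min_track_len detections are discarded. Output is sorted by
    (birth frame, track id) for determinism.
    """
    params = params or LinkParams()
    active: list[Track] = []   # open tracks, may have a trailing gap
    done: list[Track] = []
    next_id = 0
    for t, spots in enumerate(spots_by_frame):
        # retire tracks whose gap exceeded gap_max
        still = []
        for tr in active:
            if t - tr.death_frame > params.gap_max + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still

        if spots:
            if active:
                cost = np.zeros((len(active), len(spots)))
                for i, tr in enumerate(active):
                    last = np.asarray(tr.spots[-1].position)
                    for j, s in enumerate(spots):
                        cost[i, j] = np.hypot(*(last - s.position))
                big = 1e6
                cmat = np.where(cost <= params.max_link_dist_px, cost, big)
                rows, cols = linear_sum_assignment(cmat)
                matched_spots = set()
                for i, j in zip(rows, cols):
                    if cmat[i, j] < big:
                        sp = spots[j]
                        sp.frame = t if sp.frame < 0 else sp.frame
                        active[i].spots.append(sp)
                        matched_spots.add(j)
            else:
                matched_spots = set()
            for j, s in enumerate(spots):
                if j not in matched_spots:
                    s.frame = t if s.frame < 0 else s.frame
                    active.append(Track(track_id=next_id, channel=s.channel,
                                        spots=[s]))
                    next_id += 1
    done.extend(active)
    tracks = [tr for tr in done if tr.n_spots >= params.min_track_len]
    tracks.sort(key=lambda tr: (tr.birth_frame, tr.track_id))
    return tracks


# ---------------------------------------------------------------------------
# motility and exclusion


def classify_motility(track: Track, outline: CellOutline,
                      thresholds: MotilityThresholds | None = None) -> str:
    """Classify a track as static, internalizing or cytoplasmic_motile.

    Static: net displacement below static_max_net_disp_px and the track stays
    within cortex_band_px of the boundary. Internalizing: starts cortical and
    moves inward by at least inward_min_disp_px during its final quartile.
    Everything else is cytoplasmic_motile.
    """
    th = thresholds or MotilityThresholds()
    if track.n_spots < 4:
        raise UnclassifiableTrackError("track shorter than 4 frames")
    pos = track.positions()
    # endpoint positions averaged over up to 5 frames: localization jitter on
    # single frames would otherwise dominate the net displacement of a truly
    # static patch
    k = min(5, max(1, len(pos) // 4))
    net = float(np.hypot(*(pos[-k:].mean(axis=0) - pos[:k].mean(axis=0))))
    bdist = np.array([signed_boundary_distance(outline, tuple(p)) for p in pos])
    mean_abs_bdist = float(np.abs(bdist).mean())

    # internalization first: a cortical patch that moves inward at the end of
    # its lifetime is not "nonmotile", however small its net displacement
    starts_cortical = abs(bdist[0]) <= th.cortex_band_px
    q = pos[int(math.floor(0.75 * len(pos))):]
    if len(q) >= 2 and starts_cortical:
        r = np.hypot(q[:, 0] - outline.center[0], q[:, 1] - outline.center[1])
        # robust inward displacement over the final quartile: slope of a
        # straight-line fit times the window length (endpoints are noisy)
        if len(r) >= 4:
            slope = np.polyfit(np.arange(len(r)), r, 1)[0]
            inward = float(-slope * (len(r) - 1))
        else:
            inward = float(r[0] - r[-1])
        if inward >= th.inward_min_disp_px:
            return INTERNALIZING
    if net < th.static_max_net_disp_px and mean_abs_bdist <= th.cortex_band_px:
        return STATIC
    return CYTOPLASMIC_MOTILE


def exclude_crowded(tracks: list[Track], min_sep_px: float = 5.0) -> list[Track]:
    """Flag every same-channel pair of tracks that are simultaneously alive
    and ever closer than ``min_sep_px``; both members are flagged. The flag
    is set in place; already-flagged tracks stay flagged (idempotent)."""
    if min_sep_px <= 0:
        raise ValueError("min_sep_px must be positive")
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            a, b = tracks[i], tracks[j]
            if a.channel != b.channel:
                continue
            lo = max(a.birth_frame, b.birth_frame)
            hi = min(a.death_frame, b.death_frame)
            if lo > hi:
                continue
            fa = {s.frame: s.position for s in a.spots}
            fb = {s.frame: s.position for s in b.spots}
            for f in range(lo, hi + 1):
                if f in fa and f in fb:
                    if math.hypot(fa[f][0] - fb[f][0], fa[f][1] - fb[f][1]) < min_sep_px:
                        a.excluded_crowded = True
                        b.excluded_crowded = True
                        break
    return tracks
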