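"""Radial and circumferential kymographs, plus simple montages.

A radial kymograph samples a ray from the cell center through one cortical
site and shows how a single patch moves off the plasma membrane over time.
A circumferential kymograph unrolls the cell boundary and shows intensity
development at every cortical site at once: a static patch appears as a
vertical streak at its arc position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cell_geometry import CellOutline
from .errors import GeometryError


@dataclass
class Kymograph:
    """2-D space x time intensity array with axis metadata.

    For the radial flavor, ``space_axis_px`` runs along the sampling ray
    (0 at the innermost sample) and ``cortex_index`` marks the row at the
    fitted boundary. For the circumferential flavor, ``space_axis_px`` is
    arc length along the boundary.
    """

    values: np.ndarray          # (n_space, n_frames)
    flavor: str                 # "radial" | "circumferential"
    space_axis_px: np.ndarray
    frame_interval_s: float
    channel: str
    cortex_index: int | None = None
    site_angle_rad: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def radial_kymograph(movie, outline: CellOutline, site_angle: float,
                     ray_len_px: float = 10.0, width_px: int = 3,
                     channel: int | str = 0) -> Kymograph:
    """Kymograph along the ray from the cell center through the boundary at
    ``site_angle``, sampled at 1 px steps from ``ray_len_px`` inside the
    boundary to 2 px outside; each column averages ``width_px`` parallel
    samples perpendicular to the ray (bilinear interpolation)."""
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    r_b = float(outline.radius_at(site_angle))
    if not np.isfinite(r_b) or r_b <= 0:
        raise GeometryError("no boundary intersection along site_angle")
    stack = movie.channel(channel)
    cy, cx = outline.center
    u = np.array([math.sin(site_angle), math.cos(site_angle)])   # along ray
    v = np.array([math.cos(site_angle), -math.sin(site_angle)])  # perpendicular
    radii = np.arange(r_b - ray_len_px, r_b + 2.0 + 1e-9, 1.0)
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    # sample grid: (n_space * width) points
    pts = (np.array([cy, cx])[None, None]
           + radii[:, None, None] * u[None, None]
           + offsets[None, :, None] * v[None, None])
    coords = pts.reshape(-1, 2).T  # (2, n_space*width)
    n_space = len(radii)
    values = np.empty((n_space, stack.shape[0]))
    for t in range(stack.shape[0]):
        samp = ndimage.map_coordinates(stack[t], coords, order=1, mode="nearest")
        values[:, t] = samp.reshape(n_space, width_px).mean(axis=1)
    cortex_index = int(np.argmin(np.abs(radii - r_b)))
    return Kymograph(values=values, flavor="radial",
                     space_axis_px=radii - radii[0],
                     frame_interval_s=movie.frame_interval_s,
                     channel=str(channel), cortex_index=cortex_index,
                     site_angle_rad=float(site_angle),
                     meta={"ray_len_px": ray_len_px, "width_px": width_px})


def circumferential_kymograph(movie, outline: CellOutline,
                              band_half_width_px: float = 3.0,
                              channel: int | str = 0) -> Kymograph:
    """Kymograph along the unrolled boundary: at each of the outline's
    uniform arc-length positions, the value at frame t is the maximum
    intensity within a disc of radius ``band_half_width_px`` centered on the
    boundary point (maximum projection across the cortical band)."""
    if band_half_width_px < 1:
        raise ValueError("band_half_width_px must be >= 1")
    stack = movie.channel(channel)
    h, w = stack.shape[1:]
    pts = outline.boundary[:-1]
    n_pts = len(pts)
    # per boundary point: flat indices of pixels within the disc
    rad = int(math.ceil(band_half_width_px))
    dy, dx = np.mgrid[-rad - 1:rad + 2, -rad - 1:rad + 2]
    index_lists = []
    for p in pts:
        rr = np.round(p[0]).astype(int) + dy
        cc = np.round(p[1]).astype(int) + dx
        d = np.hypot(rr - p[0], cc - p[1])
        ok = (d <= band_half_width_px) & (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        index_lists.append(rr[ok] * w + cc[ok])
    values = np.empty((n_pts, stack.shape[0]))
    for t in range(stack.shape[0]):
        flat = stack[t].ravel()
        for i, idx in enumerate(index_lists):
            values[i, t] = flat[idx].max() if len(idx) else 0.0
    step = outline.arc_length_total / n_pts
    return Kymograph(values=values, flavor="circumferential",
                     space_axis_px=np.arange(n_pts) * step,
                     frame_interval_s=movie.frame_interval_s,
                     channel=str(channel),
                     meta={"band_half_width_px": band_half_width_px})


def montage(movie, roi: tuple[int, int, int, int], frame_range: tuple[int, int],
            stride: int = 1, channel: int | str = 0) -> np.ndarray:
    """Horizontal strip of cropped frames for visual QC.

    ``roi`` is (row0, row1, col0, col1); ``frame_range`` is a half-open
    (start, stop) frame interval sampled every ``stride`` frames.
    """
    r0, r1, c0, c1 = roi
    start, stop = frame_range
    frames = range(start, stop, stride)
    if len(list(frames)) == 0:
        raise ValueError("empty frame_range")
    stack = movie.channel(channel)
    if not (0 <= r0 < r1 <= stack.shape[1] and 0 <= c0 < c1 <= stack.shape[2]):
        raise ValueError("roi out of bounds")
    panels = [stack[t, r0:r1, c0:c1] for t in range(start, stop, stride)]
    return np.hstack(panels)


def ridge_positions(kymo: Kymograph) -> np.ndarray:
    """Row index of the intensity maximum per frame (radial kymographs:
    tracks the patch's distance from the cortex over time)."""
    return np.argmax(kymo.values, axis=0).astype(float)
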