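"""Cell-outline estimation and radial/angular coordinate transforms.

The cell boundary anchors both kymograph flavors and the motility
classifier: "cortical" means within a small band around the fitted outline,
and internalization is inward radial movement relative to it.

Conventions: 0-based (row, col) pixel indices with pixel centers at integer
coordinates; angles theta = atan2(row - center_row, col - center_col),
mapped to [0, 2*pi), i.e. counterclockwise from the +col axis in the
right-handed (col, row) frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_isodata
from skimage.morphology import disk

from .errors import SegmentationError


@dataclass
class CellOutline:
    """Fitted cell boundary.

    ``boundary`` is a closed polyline of (row, col) points at uniform
    arc-length spacing (last point repeats the first); points are ordered by
    increasing angle about the center.
    """

    center: tuple[float, float]
    mean_radius: float
    boundary: np.ndarray  # (N+1, 2), boundary[-1] == boundary[0]
    arc_length_total: float

    def __post_init__(self) -> None:
        if self.mean_radius <= 0:
            raise ValueError("mean_radius must be positive")
        if not np.allclose(self.boundary[0], self.boundary[-1], atol=1e-6):
            raise ValueError("boundary polyline must be closed")

    @property
    def n_points(self) -> int:
        return len(self.boundary) - 1

    def _angles_radii(self) -> tuple[np.ndarray, np.ndarray]:
        d = self.boundary[:-1] - np.asarray(self.center)
        theta = np.mod(np.arctan2(d[:, 0], d[:, 1]), 2 * math.pi)
        r = np.hypot(d[:, 0], d[:, 1])
        order = np.argsort(theta)
        return theta[order], r[order]

    def radius_at(self, theta: float | np.ndarray) -> np.ndarray:
        """Boundary radius along angle(s) theta, by circular interpolation."""
        th, r = self._angles_radii()
        th_ext = np.concatenate([th - 2 * math.pi, th, th + 2 * math.pi])
        r_ext = np.concatenate([r, r, r])
        return np.interp(np.mod(theta, 2 * math.pi), th_ext, r_ext)

    def point_at_angle(self, theta: float) -> tuple[float, float]:
        r = float(self.radius_at(theta))
        return (self.center[0] + r * math.sin(theta),
                self.center[1] + r * math.cos(theta))


def quiet_projection(stack: np.ndarray, q: float = 10.0) -> np.ndarray:
    """Per-pixel low temporal percentile of a [frame, row, col] stack.

    Cortical patches flicker on and off; as long as each pixel is patch-free
    in at least ``q`` percent of frames, the projection approximates the
    patch-free cell image and is the preferred input to
    :func:`segment_cell`. (A plain temporal mean drags the fitted outline
    outward when long-lived bright patches sit on the cortex.)
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected a [frame, row, col] stack")
    return np.percentile(stack, q, axis=0)


def segment_cell(frame: np.ndarray, min_area: int = 50,
                 n_boundary_points: int | None = None) -> CellOutline:
    """Segment the single cell in ``frame`` and fit its outline.

    Threshold by Otsu's method (splits exterior background from the brighter
    cell interior at the midpoint, so a smooth cell edge is cut at its
    half-level), keep the largest connected component, fill holes, then
    extract a subpixel contour and resample it to uniform arc-length spacing
    (default ~1 px). Best applied to a time-averaged frame so patch flicker
    does not distort the outline.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) <= 0:
        raise SegmentationError("frame has no contrast")
    # grey-scale opening removes bright blobs narrower than the footprint
    # (cortical patches and their halos) while leaving the convex cell body
    # intact, so the outline does not bulge at patch sites
    smooth = ndimage.grey_opening(frame, footprint=disk(5))
    smooth = ndimage.median_filter(smooth, size=3)
    if np.ptp(smooth) <= 0:
        raise SegmentationError("frame has no contrast")
    thr = threshold_isodata(smooth)
    mask = smooth > thr
    labels, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        raise SegmentationError(
            f"largest component has area {int(sizes[best - 1])} < {min_area}"
        )
    cell = ndimage.binary_fill_holes(labels == best)

    contours = measure.find_contours(cell.astype(float), 0.5)
    contour = max(contours, key=len)
    rows, cols = np.nonzero(cell)
    center = (float(rows.mean()), float(cols.mean()))

    # order by angle about the center, then resample at uniform arc length
    d = contour - center
    theta = np.mod(np.arctan2(d[:, 0], d[:, 1]), 2 * math.pi)
    order = np.argsort(theta)
    pts = contour[order]
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(arc[-1])
    n_pts = n_boundary_points or max(8, int(round(total)))
    s = np.linspace(0.0, total, n_pts, endpoint=False)
    rr = np.interp(s, arc, closed[:, 0])
    cc = np.interp(s, arc, closed[:, 1])

    # de-bulge: bright cortical patches locally push the threshold contour
    # outward; a circular grey opening on the radius-vs-position profile
    # removes those outward excursions and leaves a smooth edge unchanged
    radii = np.hypot(rr - center[0], cc - center[1])
    if n_pts >= 24:
        win = max(9, n_pts // 8)
        radii_open = ndimage.grey_opening(radii, size=win, mode="wrap")
        theta = np.arctan2(rr - center[0], cc - center[1])
        rr = center[0] + radii_open * np.sin(theta)
        cc = center[1] + radii_open * np.cos(theta)

    # re-resample so spacing stays uniform after de-bulging
    closed2 = np.column_stack([rr, cc])
    closed2 = np.vstack([closed2, closed2[:1]])
    seg2 = np.hypot(*np.diff(closed2, axis=0).T)
    arc2 = np.concatenate([[0.0], np.cumsum(seg2)])
    total = float(arc2[-1])
    n_pts = n_boundary_points or max(8, int(round(total)))
    s2 = np.linspace(0.0, total, n_pts, endpoint=False)
    boundary = np.column_stack([np.interp(s2, arc2, closed2[:, 0]),
                                np.interp(s2, arc2, closed2[:, 1])])
    boundary = np.vstack([boundary, boundary[:1]])
    mean_radius = float(np.hypot(*(boundary[:-1] - center).T).mean())
    return CellOutline(center, mean_radius, boundary, total)


def circular_outline(center: tuple[float, float], radius: float,
                     n_points: int | None = None) -> CellOutline:
    """Analytic circular outline (synthetic cells, tests, defaults)."""
    n = n_points or max(8, int(round(2 * math.pi * radius)))
    theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
    boundary = np.column_stack([center[0] + radius * np.sin(theta),
                                center[1] + radius * np.cos(theta)])
    boundary = np.vstack([boundary, boundary[:1]])
    return CellOutline(tuple(center), float(radius), boundary,
                       float(2 * math.pi * radius))


def radial_coordinate(outline: CellOutline, point: tuple[float, float]
                      ) -> tuple[float, float]:
    """Normalized radius and angle of ``point`` relative to the outline.

    r_norm is the distance from the center divided by the boundary radius
    along the same angle; the cell center maps to (0, 0) by convention.
    """
    dy = point[0] - outline.center[0]
    dx = point[1] - outline.center[1]
    dist = math.hypot(dy, dx)
    if dist < 1e-12:
        return 0.0, 0.0
    theta = math.atan2(dy, dx) % (2 * math.pi)
    r_local = float(outline.radius_at(theta))
    return dist / r_local, theta


def signed_boundary_distance(outline: CellOutline, point: tuple[float, float]
                             ) -> float:
    """Radial distance of ``point`` from the boundary (negative inside)."""
    r_norm, theta = radial_coordinate(outline, point)
    return (r_norm - 1.0) * float(outline.radius_at(theta))


def boundary_band_mask(outline: CellOutline, half_width_px: float,
                       shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``half_width_px`` of
    the boundary polyline (the "cortical" band)."""
    if half_width_px < 0:
        raise ValueError("half_width_px must be >= 0")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    d = _min_dist_to_polyline(pts, outline.boundary).reshape(h, w)
    return d <= max(half_width_px, 0.5)


def _min_dist_to_polyline(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Exact minimum distance from each point to the closed polyline."""
    a = polyline[:-1]  # (M, 2) segment starts
    b = polyline[1:]   # (M, 2) segment ends
    ab = b - a
    ab2 = np.maximum((ab**2).sum(axis=1), 1e-12)
    best = np.full(len(points), np.inf)
    # chunk over segments to bound memory
    for i in range(0, len(a), 256):
        aa, bb = a[i:i + 256], ab[i:i + 256]
        ap = points[:, None, :] - aa[None, :, :]
        t = np.clip((ap * bb[None]).sum(axis=2) / ab2[i:i + 256][None], 0.0, 1.0)
        proj = aa[None] + t[:, :, None] * bb[None]
        d = np.hypot(points[:, None, 0] - proj[:, :, 0],
                     points[:, None, 1] - proj[:, :, 1])
        best = np.minimum(best, d.min(axis=1))
    return best
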