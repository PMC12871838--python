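"""Slice-mask centerlines, B-spline contour fits, and analytic curvature.

Each 2D membrane cross-section is reduced to a single-pixel-wide centerline
by morphological thinning, ordered into an open arc by nearest-neighbour
traversal from the endpoint closest to the image border (closed loops are cut
open there), and fitted with a smoothing cubic B-spline sampled at 200
uniformly spaced parameter values. Signed curvature comes from the analytic
spline derivatives,

    kappa = (x' y'' - y' x'') / (x'^2 + y'^2)^(3/2)   [px^-1].

Arcs whose spline arc length is below ``MIN_ARC_PX`` (50 px) are excluded
from downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.interpolate import splev, splprep
from skimage.morphology import thin

#: arc-length exclusion threshold, px (strict: arcs shorter than this drop)
MIN_ARC_PX = 50.0

#: number of uniformly spaced parameter samples along each spline
N_SPLINE_SAMPLES = 200

#: skeleton branches shorter than this (px) off the main path are spurs
SPUR_LENGTH_PX = 5


class ContourRejected(ValueError):
    """Raised when a slice contour cannot enter downstream analysis."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class SliceContour:
    """Ordered open-arc centerline of one z-slice."""

    z_index: int
    points: np.ndarray  # (n, 2) as (x, y) pixel coordinates
    was_closed: bool = False

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SplineCurve:
    """Cubic B-spline fit of an ordered contour, sampled at 200 parameters."""

    tck: tuple
    smoothing_value: float
    samples: np.ndarray       # (200, 2)
    first_deriv: np.ndarray   # (200, 2) analytic d/du
    second_deriv: np.ndarray  # (200, 2) analytic d2/du2
    arc_length_px: float


@dataclass
class CurvatureProfile:
    """Signed curvature per spline sample, px^-1."""

    kappa: np.ndarray
    abs_mean: float = field(init=False)
    abs_max: float = field(init=False)

    def __post_init__(self) -> None:
        a = np.abs(self.kappa[np.isfinite(self.kappa)])
        self.abs_mean = float(a.mean()) if a.size else float("nan")
        self.abs_max = float(a.max()) if a.size else float("nan")


def skeletonize_slice(mask: np.ndarray) -> np.ndarray:
    """Reduce a binary mask to a unit-width centerline by morphological thinning."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("skeletonize_slice: empty mask", stacklevel=2)
        return np.zeros_like(mask)
    return thin(mask)


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    pts = set(map(tuple, np.argwhere(skel)))
    g = nx.Graph()
    g.add_nodes_from(pts)
    for (y, x) in pts:
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dy, dx) != (0, 0) and (y + dy, x + dx) in pts:
                    g.add_edge((y, x), (y + dy, x + dx))
    return g


def _border_distance(p: tuple[int, int], shape: tuple[int, int]) -> int:
    y, x = p
    return min(y, x, shape[0] - 1 - y, shape[1] - 1 - x)


def order_skeleton_points(
    skel: np.ndarray, image_shape: tuple[int, int] | None = None, z_index: int = 0
) -> SliceContour:
    """Order skeleton pixels along the curve by nearest-neighbour traversal.

    The centerline is the longest geodesic (endpoint-to-endpoint) path of the
    skeleton graph; shorter branches are treated as spurs and pruned.
    Traversal starts at the path endpoint nearest the image border. Skeletons
    without endpoints (closed loops) are cut open at the pixel nearest the
    border and flagged ``was_closed``. If several connected components exist,
    the largest is kept and a warning is emitted.
    """
    skel = np.asarray(skel, dtype=bool)
    shape = image_shape or skel.shape
    if not skel.any():
        raise ContourRejected("empty_skeleton")
    g = _skeleton_graph(skel)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        warnings.warn(
            f"skeleton has {len(comps)} components; keeping largest", stacklevel=2
        )
        g = g.subgraph(max(comps, key=len)).copy()
    if g.number_of_nodes() == 1:
        (p,) = g.nodes
        return SliceContour(z_index, np.array([[p[1], p[0]]], float), False)

    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    was_closed = False
    if endpoints:
        # longest geodesic between endpoints = main path; spurs pruned
        best = None
        for e in endpoints:
            lengths = nx.single_source_shortest_path_length(g, e)
            far = max(
                (n for n in lengths if g.degree(n) == 1),
                key=lambda n: lengths[n],
                default=e,
            )
            if best is None or lengths[far] > best[2]:
                best = (e, far, lengths[far])
        a, b, _ = best
        path = nx.shortest_path(g, a, b)
        start, end = (a, b) if (
            _border_distance(a, shape) <= _border_distance(b, shape)
        ) else (b, a)
        path = path if path[0] == start else path[::-1]
    else:
        # closed loop: cut at the pixel nearest the border
        was_closed = True
        start = min(g.nodes, key=lambda p: _border_distance(p, shape))
        path = [start]
        seen = {start}
        cur = start
        while True:
            nbrs = [n for n in g.neighbors(cur) if n not in seen]
            if not nbrs:
                break
            cur = min(
                nbrs,
                key=lambda n: (n[0] - path[-1][0]) ** 2 + (n[1] - path[-1][1]) ** 2,
            )
            path.append(cur)
            seen.add(cur)
    pts = np.array([[x, y] for (y, x) in path], dtype=float)
    return SliceContour(z_index=z_index, points=pts, was_closed=was_closed)


def _noise_variance(x: np.ndarray, y: np.ndarray) -> float:
    """Per-point jitter variance (2D total) from third differences.

    Third differences annihilate smooth (locally cubic) trends, so for a
    smooth contour the estimate tends to zero while for an iid-jittered one
    it converges to the jitter variance (coefficient variance sums to 20).
    """
    if len(x) < 6:
        return 0.0
    ex = x[3:] - 3 * x[2:-1] + 3 * x[1:-2] - x[:-3]
    ey = y[3:] - 3 * y[2:-1] + 3 * y[1:-2] - y[:-3]
    return float(np.mean(ex**2 + ey**2) / 20.0)


def fit_spline(contour: SliceContour, n_samples: int = N_SPLINE_SAMPLES) -> SplineCurve:
    """Fit a smoothing cubic B-spline to an ordered contour.

    The smoothing value follows the point-density heuristic
    ``s = (m - sqrt(2 m)) * var`` with ``var`` the estimated per-point jitter
    variance, so noise-free contours are interpolated while pixel-jittered
    skeletons are smoothed at the jitter scale.

    Raises
    ------
    ContourRejected
        If fewer than 4 distinct points are available (cubic requirement).
    """
    pts = np.asarray(contour.points, dtype=float)
    # splprep requires strictly distinct consecutive points
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[keep]
    m = len(pts)
    if m < 4:
        raise ContourRejected("too_short")
    x, y = pts[:, 0], pts[:, 1]
    s = max(m - np.sqrt(2.0 * m), 0.0) * _noise_variance(x, y)
    tck, _ = splprep([x, y], s=s, k=3)
    u = np.linspace(0.0, 1.0, n_samples)
    sx, sy = splev(u, tck)
    dx, dy = splev(u, tck, der=1)
    ddx, ddy = splev(u, tck, der=2)
    samples = np.column_stack([sx, sy])
    arc = float(np.sum(np.hypot(np.diff(sx), np.diff(sy))))
    return SplineCurve(
        tck=tck,
        smoothing_value=float(s),
        samples=samples,
        first_deriv=np.column_stack([dx, dy]),
        second_deriv=np.column_stack([ddx, ddy]),
        arc_length_px=arc,
    )


def signed_curvature(spline: SplineCurve) -> CurvatureProfile:
    """Signed curvature at every spline sample from analytic derivatives.

    Samples with vanishing speed are reported as NaN rather than infinite.
    The sign follows the traversal orientation (arbitrary for open arcs);
    summaries therefore use |kappa|.
    """
    dx, dy = spline.first_deriv.T
    ddx, ddy = spline.second_deriv.T
    speed2 = dx**2 + dy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dx * ddy - dy * ddx) / speed2**1.5
    kappa = np.where(speed2 > 0, kappa, np.nan)
    return CurvatureProfile(kappa=kappa)


def slice_shape_metrics(spline: SplineCurve) -> dict:
    """Perimeter, bounding box, aspect ratio and centroid of a spline fit.

    Perimeter is the spline arc length; box and centroid are computed over
    the 200 spline samples; aspect_ratio = long / short side (>= 1, inf for
    degenerate zero-height boxes).
    """
    xy = spline.samples
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    w, h = hi - lo
    long_side, short_side = max(w, h), min(w, h)
    aspect = float(long_side / short_side) if short_side > 0 else float("inf")
    cx, cy = xy.mean(axis=0)
    return {
        "perimeter_px": spline.arc_length_px,
        "bbox_w": float(w),
        "bbox_h": float(h),
        "aspect_ratio": aspect,
        "centroid": (float(cx), float(cy)),
    }


def passes_length_filter(
    spline: SplineCurve, min_arc_px: float = MIN_ARC_PX, strict: bool = True
) -> bool:
    """True iff the spline arc length passes the exclusion threshold.

    Strict reading: arcs *below* ``min_arc_px`` are excluded, so exactly
    50 px is retained.
    """
    if strict:
        return spline.arc_length_px >= min_arc_px
    return spline.arc_length_px > min_arc_px
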