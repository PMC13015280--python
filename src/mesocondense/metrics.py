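"""Spatial quantifications for point sets (cell centroids) and polylines
(epithelial outlines).

Everything here is pure geometry/statistics, usable on simulation output
or on externally segmented micrograph data. Coordinates are unit-agnostic;
a declared unit string travels with the containers and into summaries.
Nearest-point computations use full segments (not vertices only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike, NDArray
from shapely.geometry import LineString, Point

from .params import MorphogenSource

__all__ = [
    "PointSet",
    "Polyline",
    "density_field",
    "radial_profile",
    "detect_condensation",
    "CondensationCall",
    "bead_branch_distance",
    "branch_spacing",
    "cdf_along_branch",
    "roi_count",
]


@dataclass
class PointSet:
    """2D points with optional per-point marks (e.g. EdU-positive)."""

    points: NDArray
    labels: NDArray | None = None
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.points):
                raise ValueError("labels must match points in length")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Polyline:
    """Ordered vertices of a branch outline.

    ``tip_index`` marks the vertex used as the arclength origin (the
    branch tip); required by :func:`cdf_along_branch`.
    """

    vertices: NDArray
    closed: bool = False
    tip_index: int | None = None
    units: str = "dimensionless"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if len(self.vertices) < 2:
            raise ValueError("polyline needs at least 2 vertices")
        seg = np.diff(self.vertices, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise ValueError("consecutive vertices must be distinct")

    def line(self) -> LineString:
        v = self.vertices
        if self.closed:
            v = np.vstack([v, v[:1]])
        return LineString(v)

    def arclengths(self) -> NDArray:
        """Cumulative arclength at each vertex, starting at 0."""
        seg = np.diff(self.vertices, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])


def density_field(
    points: PointSet | ArrayLike,
    grid_spacing: float,
    bandwidth: float,
    extent: tuple[float, float, float, float] | None = None,
) -> tuple[NDArray, NDArray, NDArray]:
    """Gaussian-kernel density on a regular grid (mass-normalized).

    The field integrates to the number of points: each point contributes
    an isotropic Gaussian of the given bandwidth (sigma). Returns
    ``(density, x_centers, y_centers)`` with density indexed [iy, ix].
    By default the grid covers the bounding box padded by 4 bandwidths.
    """
    if grid_spacing <= 0 or bandwidth <= 0:
        raise ValueError("grid_spacing and bandwidth must be positive")
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, float).reshape(-1, 2)
    if extent is None:
        if len(pts) == 0:
            extent = (0.0, 1.0, 0.0, 1.0)
        else:
            pad = 4 * bandwidth
            extent = (
                pts[:, 0].min() - pad,
                pts[:, 0].max() + pad,
                pts[:, 1].min() - pad,
                pts[:, 1].max() + pad,
            )
    x0, x1, y0, y1 = extent
    xs = np.arange(x0 + grid_spacing / 2, x1, grid_spacing)
    ys = np.arange(y0 + grid_spacing / 2, y1, grid_spacing)
    dens = np.zeros((len(ys), len(xs)))
    if len(pts) == 0:
        return dens, xs, ys
    norm = 1.0 / (2 * np.pi * bandwidth**2)
    # separable kernel: outer product of 1D Gaussians per point, chunked
    gx = np.exp(-0.5 * ((xs[None, :] - pts[:, 0, None]) / bandwidth) ** 2)
    gy = np.exp(-0.5 * ((ys[None, :] - pts[:, 1, None]) / bandwidth) ** 2)
    dens = norm * (gy.T @ gx)
    return dens, xs, ys


def radial_profile(
    points: PointSet | ArrayLike,
    center: ArrayLike,
    bin_width: float,
    r_max: float,
) -> tuple[NDArray, NDArray]:
    """Area-normalized point density per concentric annulus around ``center``.

    Returns ``(bin_edges, density)`` with ``density[k]`` the count in
    annulus [edges[k], edges[k+1]) divided by its area.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, float).reshape(-1, 2)
    center = np.asarray(center, dtype=float)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    if len(pts) == 0:
        return edges, np.zeros(len(edges) - 1)
    r = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    counts, _ = np.histogram(r, bins=edges)
    areas = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    return edges, counts / areas


@dataclass(frozen=True)
class CondensationCall:
    """Result of :func:`detect_condensation`."""

    present: bool
    index: float  # nan when undefined
    n_inside: int
    n_outside: int

    @property
    def undefined(self) -> bool:
        return math.isnan(self.index)


def detect_condensation(
    points: PointSet | ArrayLike,
    center: ArrayLike,
    region_radius: float,
    threshold_ratio: float = 1.5,
    domain_area: float | None = None,
    excluded_area: float = 0.0,
) -> CondensationCall:
    """Call a condensation from the near-source / far-field density ratio.

    index = (n_inside / region area) / (n_outside / outside area). The
    outside area is ``domain_area`` minus the region disk; when
    ``domain_area`` is None the bounding-box area of the points is used.
    ``excluded_area`` (e.g. the bead disk) is subtracted from the region
    area. ``present`` iff index >= threshold_ratio; the index is NaN
    (and the call negative) when either density is undefined.
    """
    if threshold_ratio <= 1:
        raise ValueError("threshold_ratio must exceed 1")
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, float).reshape(-1, 2)
    if len(pts) == 0:
        return CondensationCall(False, float("nan"), 0, 0)
    center = np.asarray(center, dtype=float)
    r = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1])
    n_in = int(np.count_nonzero(r < region_radius))
    n_out = len(pts) - n_in
    region_area = np.pi * region_radius**2 - excluded_area
    if domain_area is None:
        span = pts.max(axis=0) - pts.min(axis=0)
        domain_area = float(span[0] * span[1])
    outside_area = domain_area - np.pi * region_radius**2
    if n_out == 0 or outside_area <= 0 or region_area <= 0:
        return CondensationCall(False, float("nan"), n_in, n_out)
    index = (n_in / region_area) / (n_out / outside_area)
    return CondensationCall(bool(index >= threshold_ratio), float(index), n_in, n_out)


def bead_branch_distance(source: MorphogenSource, chain: Polyline | ArrayLike) -> float:
    """Minimum distance from the bead surface to the branch outline.

    Measured over full chain segments, minus the bead radius, floored at
    zero (contact).
    """
    if not isinstance(chain, Polyline):
        chain = Polyline(np.asarray(chain, float))
    d = chain.line().distance(Point(source.center))
    return max(d - source.bead_radius, 0.0)


def branch_spacing(
    chain_a: Polyline,
    chain_b: Polyline,
    window: tuple[float, float] | None = None,
) -> dict:
    """Per-vertex distance from branch A to the nearest point of branch B.

    ``window`` is an arclength interval on A (measured from ``tip_index``
    if set, else from vertex 0); only A-vertices inside it enter the
    profile. Returns ``{"arclength", "profile", "mean", "sd"}`` with the
    profile ordered by arclength from the tip.
    """
    s = chain_a.arclengths()
    order = np.arange(len(s))
    if chain_a.tip_index not in (None, 0):
        if chain_a.tip_index != len(s) - 1:
            raise ValueError("tip_index must be an endpoint of the branch")
        # re-origin arclength at the tip by reversing orientation
        s = s[-1] - s
        order = order[::-1]
        s = s[::-1]
    if window is not None:
        lo, hi = window
        if lo > hi or hi < s.min() or lo > s.max():
            raise ValueError("empty arclength window")
        mask = (s >= lo) & (s <= hi)
        if not np.any(mask):
            raise ValueError("empty arclength window")
    else:
        mask = np.ones(len(s), dtype=bool)
    line_b = chain_b.line()
    verts = chain_a.vertices[order][mask]
    prof = np.array([line_b.distance(Point(p)) for p in verts])
    return {
        "arclength": s[mask],
        "profile": prof,
        "mean": float(prof.mean()),
        "sd": float(prof.std()),
    }


def cdf_along_branch(
    marked: PointSet, branch: Polyline
) -> tuple[NDArray, NDArray]:
    """CDF of marked points over normalized arclength from the branch tip.

    Each point is projected to its nearest position on the branch;
    positions are normalized so 0 is the tip (``tip_index``) and 1 the
    far end. Projection ties resolve to the smaller arclength. Returns
    ``(sorted positions, cdf)``; the CDF is non-decreasing and ends at 1.
    """
    if branch.tip_index is None:
        raise ValueError("branch needs a tip_index to define the arclength origin")
    if len(marked) == 0:
        raise ValueError("CDF of zero marked points is undefined")
    if branch.tip_index not in (0, len(branch.vertices) - 1):
        raise ValueError("tip_index must be an endpoint of the branch")
    line = branch.line()
    total = line.length
    s = np.array([line.project(Point(p)) for p in marked.points]) / total
    if branch.tip_index != 0:  # tip at the far end: measure from there
        s = 1.0 - s
    s.sort()
    cdf = np.arange(1, len(s) + 1) / len(s)
    return s, cdf


def roi_count(
    points: PointSet | ArrayLike, roi: tuple[float, float, float, float]
) -> dict:
    """Count points in the half-open rectangle [x0, x1) x [y0, y1).

    The half-open convention makes a tiling of ROIs partition points
    exactly. Returns ``{"count", "area_normalized_density"}``.
    """
    x0, x1, y0, y1 = roi
    area = (x1 - x0) * (y1 - y0)
    if area <= 0:
        raise ValueError("roi must have positive area")
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, float).reshape(-1, 2)
    if len(pts) == 0:
        n = 0
    else:
        inside = (
            (pts[:, 0] >= x0)
            & (pts[:, 0] < x1)
            & (pts[:, 1] >= y0)
            & (pts[:, 1] < y1)
        )
        n = int(np.count_nonzero(inside))
    return {"count": n, "area_normalized_density": n / area}
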