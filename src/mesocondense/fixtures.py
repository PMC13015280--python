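"""Seeded generators of synthetic point patterns and branch outlines.

These stand in for segmented micrograph data: uniform background clouds,
locally condensed (Gaussian-enriched) clouds around a known center, and
parallel branch pairs with marked points distributed along arclength
(tip-enriched or uniform). Every bundle carries the ground-truth
generator parameters so expected metric values can be computed
analytically in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import NDArray

from .metrics import PointSet, Polyline

# decay scale of the tip-enriched mark distribution, as a fraction of
# branch length (truncated exponential from the tip)
TIP_DECAY_SCALE = 0.15


@dataclass
class FixtureBundle:
    """A generated input plus the truth that produced it."""

    pointset: PointSet | None
    polylines: list[Polyline]
    truth: dict[str, Any]
    seed: int


def gen_uniform_points(n: int, box: tuple[float, float], seed: int) -> FixtureBundle:
    """n i.i.d. uniform points in a box (no condensation)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0.0, 0.0], list(box), size=(n, 2)) if n else np.empty((0, 2))
    truth = {"kind": "uniform", "n": n, "box": list(box), "condensed": False}
    return FixtureBundle(PointSet(pts), [], truth, seed)


def gen_condensation_points(
    n_bg: int,
    n_cond: int,
    center: tuple[float, float],
    sigma: float,
    box: tuple[float, float],
    seed: int,
) -> FixtureBundle:
    """Uniform background plus an isotropic Gaussian cluster at ``center``.

    Gaussian draws falling outside the box are redrawn (rejection
    clipping), so the cluster stays inside the domain. The truth records
    the center, sigma and the enrichment achieved within 2 sigma.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    bg = rng.uniform([0.0, 0.0], list(box), size=(n_bg, 2)) if n_bg else np.empty((0, 2))
    cond = np.empty((0, 2))
    center_arr = np.asarray(center, dtype=float)
    while len(cond) < n_cond:
        draw = center_arr + sigma * rng.standard_normal((n_cond - len(cond), 2))
        ok = np.all((draw >= 0) & (draw <= box), axis=1)
        cond = np.vstack([cond, draw[ok]])
    pts = np.vstack([bg, cond])
    labels = np.concatenate([np.zeros(n_bg, dtype=int), np.ones(n_cond, dtype=int)])
    r = np.hypot(pts[:, 0] - center_arr[0], pts[:, 1] - center_arr[1])
    disk = np.pi * (2 * sigma) ** 2
    n_in = int(np.count_nonzero(r < 2 * sigma))
    n_out = len(pts) - n_in
    out_area = box[0] * box[1] - disk
    enrichment = (n_in / disk) / (n_out / out_area) if n_out else float("inf")
    truth = {
        "kind": "condensation",
        "n_bg": n_bg,
        "n_cond": n_cond,
        "center": list(center),
        "sigma": sigma,
        "box": list(box),
        "condensed": n_cond > 0,
        "achieved_enrichment_2sigma": float(enrichment),
    }
    return FixtureBundle(PointSet(pts, labels=labels), [], truth, seed)


def gen_branch_pair(
    spacing: float,
    length: float,
    n_marks: int,
    mark_mode: str = "uniform",
    seed: int = 0,
    n_vertices: int = 50,
    decay_scale: float = TIP_DECAY_SCALE,
) -> FixtureBundle:
    """Two parallel open branches with marks along branch A.

    Branches run along x from the shared tip at x = 0 (tip_index = 0) to
    x = length, separated by ``spacing`` in y. Marks lie exactly on
    branch A at arclengths drawn either uniformly or from a truncated
    exponential decaying from the tip with scale ``decay_scale * length``.
    """
    if spacing <= 0 or length <= 0:
        raise ValueError("spacing and length must be positive")
    if mark_mode not in ("uniform", "tip_enriched"):
        raise ValueError("mark_mode must be 'uniform' or 'tip_enriched'")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, length, n_vertices)
    branch_a = Polyline(np.column_stack([x, np.zeros_like(x)]), tip_index=0)
    branch_b = Polyline(np.column_stack([x, np.full_like(x, spacing)]), tip_index=0)
    u = rng.uniform(size=n_marks)
    if mark_mode == "uniform":
        s = u * length
    else:
        scale = decay_scale * length
        # inverse-CDF of an exponential truncated at the branch length
        s = -scale * np.log1p(-u * (1.0 - np.exp(-length / scale)))
    marks = PointSet(np.column_stack([s, np.zeros_like(s)]))
    truth = {
        "kind": "branch_pair",
        "spacing": spacing,
        "length": length,
        "n_marks": n_marks,
        "mark_mode": mark_mode,
        "decay_scale": decay_scale,
    }
    return FixtureBundle(marks, [branch_a, branch_b], truth, seed)
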