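"""Pairwise repulsion, chemotactic polarity update and overdamped velocities.

Pure functions only — no time stepping, no state mutation. The scalar
signatures mirror the model equations one-to-one; `*_many` variants are
vectorized forms used by the engine.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .params import MorphogenSource, SimulationParams

__all__ = [
    "repulsion_magnitude",
    "pair_repulsion",
    "net_interaction_force",
    "polarity_update",
    "polarity_update_many",
    "mesenchymal_velocity",
    "bead_repulsion_many",
]

# Floor used when two agents coincide: they are nudged apart by a seeded
# jitter of this fraction of d_c instead of raising mid-run.
COINCIDENCE_JITTER = 1e-6


class DegeneratePairError(ValueError):
    """Two interacting agents at identical positions."""


def repulsion_magnitude(r: ArrayLike, k_rep: float, d_c: float, lam: float) -> NDArray:
    """Scalar repulsion profile k_rep * f(r).

    f(r) = r/lam + (d_c/r)^lam - d_c/lam - 1 for 0 < r < d_c, else 0.
    f vanishes continuously at the cutoff, diverges at contact, and is
    strictly decreasing on (0, d_c].
    """
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    inside = (r > 0) & (r < d_c)
    ri = r[inside]
    out[inside] = k_rep * (ri / lam + (d_c / ri) ** lam - d_c / lam - 1.0)
    return out


def pair_repulsion(
    xi: ArrayLike, xj: ArrayLike, k_rep: float, d_c: float, lam: float
) -> NDArray:
    """Repulsive force on agent i from agent j, directed from j toward i.

    Zero beyond the cutoff ``d_c``. Raises :class:`DegeneratePairError`
    for coincident agents (the engine jitters those before calling).
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    dx = xi - xj
    r = float(np.hypot(dx[0], dx[1]))
    if r == 0.0:
        raise DegeneratePairError("coincident agents have no defined direction")
    mag = float(repulsion_magnitude(r, k_rep, d_c, lam))
    return mag / r * dx


def net_interaction_force(
    agent_index: int, positions: ArrayLike, params: SimulationParams
) -> NDArray:
    """Sum of pair repulsions on one agent from all others within ``d_c``.

    Direct O(N) reference implementation; the engine uses a KD-tree
    neighbor query that is tested against this form.
    """
    positions = np.asarray(positions, dtype=float)
    xi = positions[agent_index]
    dx = xi[None, :] - positions
    r = np.hypot(dx[:, 0], dx[:, 1])
    r[agent_index] = np.inf
    if np.any(r == 0.0):
        raise DegeneratePairError("coincident agents in configuration")
    mag = repulsion_magnitude(r, params.k_rep, params.d_c, params.lam)
    with np.errstate(invalid="ignore"):
        scale = np.where(mag > 0, mag / r, 0.0)
    return (scale[:, None] * dx).sum(axis=0)


def _bearing(dx: NDArray, dy: NDArray) -> NDArray:
    return np.arctan2(dy, dx)


def wrap_angle(theta: ArrayLike) -> NDArray:
    """Wrap angles into (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    wrapped = np.remainder(-theta + np.pi, 2 * np.pi)
    return -(wrapped - np.pi)


def polarity_update_many(
    theta: NDArray,
    positions: NDArray,
    source: MorphogenSource | None,
    alpha: float,
    noise: NDArray | float = 0.0,
) -> NDArray:
    """New polarity angles after one step of chemotaxis plus noise.

    Inside the source-adjacent region (d < R) the angle turns toward the
    bearing phi of the source by alpha * (1 - d/R) * sin(phi - theta);
    everywhere the rotational noise term is added. A cell exactly at the
    source center keeps its angle (bearing undefined). Result wrapped to
    (-pi, pi].
    """
    theta = np.asarray(theta, dtype=float)
    new = theta + np.asarray(noise, dtype=float)
    if source is not None and alpha > 0:
        cx, cy = source.center
        dx = cx - positions[:, 0]
        dy = cy - positions[:, 1]
        d = np.hypot(dx, dy)
        in_region = (d < source.region_radius) & (d > 0)
        if np.any(in_region):
            phi = _bearing(dx[in_region], dy[in_region])
            gain = alpha * (1.0 - d[in_region] / source.region_radius)
            new[in_region] = new[in_region] + gain * np.sin(phi - theta[in_region])
    return wrap_angle(new)


def polarity_update(
    theta: float,
    position: ArrayLike,
    source: MorphogenSource | None,
    alpha: float,
    rng: np.random.Generator | None = None,
    noise_std: float = 0.0,
) -> float:
    """Single-cell polarity update; see :func:`polarity_update_many`."""
    noise = 0.0
    if rng is not None and noise_std > 0:
        noise = noise_std * rng.standard_normal()
    pos = np.asarray(position, dtype=float)[None, :]
    return float(polarity_update_many(np.array([theta]), pos, source, alpha, noise)[0])


def mesenchymal_velocity(
    theta: float, F_net: ArrayLike, params: SimulationParams
) -> NDArray:
    """Overdamped velocity gamma_m * (v0 * n + F) of a mesenchymal cell."""
    n = np.array([np.cos(theta), np.sin(theta)])
    return params.gamma_m * (params.v0 * n + np.asarray(F_net, dtype=float))


def bead_repulsion_many(
    positions: NDArray, source: MorphogenSource, params: SimulationParams
) -> NDArray:
    """Repulsion of agents from the bead obstacle.

    Each agent interacts with the nearest point of the bead surface via
    the same kernel as cell-cell repulsion; the force is radial from the
    bead center. Agents at or inside the surface are pushed outward with
    the near-contact magnitude.
    """
    out = np.zeros_like(positions)
    if source.bead_radius <= 0:
        return out
    cx, cy = source.center
    dx = positions[:, 0] - cx
    dy = positions[:, 1] - cy
    r = np.hypot(dx, dy)
    s = r - source.bead_radius  # distance to bead surface
    active = (s < params.d_c) & (r > 0)
    if not np.any(active):
        return out
    s_eff = np.clip(s[active], COINCIDENCE_JITTER * params.d_c, None)
    mag = repulsion_magnitude(s_eff, params.k_rep, params.d_c, params.lam)
    ux = dx[active] / r[active]
    uy = dy[active] / r[active]
    out[active, 0] = mag * ux
    out[active, 1] = mag * uy
    return out
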