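"""Deformable closed-chain epithelium: geometry and vertex forces.

An epithelial branch is a closed loop of vertices (vertex i neighbors
i-1 and i+1 modulo n). Three internal forces act on each vertex:

* bending  F_b = k_b [ (psi_{i-1}-psi_i)/|x_i - x_{i-1}| n_{i-1}
                       + (psi_{i+1}-psi_i)/|x_{i+1} - x_i| n_i ]
* tension  F_t: restoring springs on both adjacent edges with rest
  length l0 (a stretched edge pulls the vertex toward that neighbor)
* pressure F_p = k_p (n_{i-1} + n_i), with n the outward edge normal,
  so positive k_p inflates the lumen.

psi_i is the signed turning angle from edge (x_i - x_{i-1}) to edge
(x_{i+1} - x_i), counter-clockwise positive. Normals are oriented
outward from the loop interior via the signed area of the polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray


class DegenerateChainError(ValueError):
    """A chain edge has zero length."""


@dataclass
class EpithelialChain:
    """Ordered closed loop of epithelial vertex positions.

    ``l0`` is the resting edge length, set at initialization (by the
    constructors below it is the initial mean edge length).
    """

    id: int
    vertices: NDArray
    l0: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if len(self.vertices) < 4:
            raise ValueError("a closed chain needs at least 4 vertices")
        if not self.l0 > 0:
            raise ValueError("l0 must be positive")
        if np.any(edge_lengths(self.vertices) == 0):
            raise DegenerateChainError("consecutive vertices coincide")

    @property
    def n(self) -> int:
        return len(self.vertices)

    def copy(self) -> "EpithelialChain":
        return EpithelialChain(self.id, self.vertices.copy(), self.l0)


def edges(vertices: NDArray) -> NDArray:
    """Edge vectors e_i = x_{i+1} - x_i (closed indexing)."""
    return np.roll(vertices, -1, axis=0) - vertices


def edge_lengths(vertices: NDArray) -> NDArray:
    e = edges(vertices)
    return np.hypot(e[:, 0], e[:, 1])


def signed_area(vertices: NDArray) -> float:
    """Shoelace area; positive for counter-clockwise loops."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def turning_angles(vertices: NDArray) -> NDArray:
    """Signed turning angle psi_i at every vertex, CCW positive, in (-pi, pi]."""
    e = edges(vertices)
    if np.any(np.hypot(e[:, 0], e[:, 1]) == 0):
        raise DegenerateChainError("zero-length edge")
    e_prev = np.roll(e, 1, axis=0)  # edge (x_i - x_{i-1})
    cross = e_prev[:, 0] * e[:, 1] - e_prev[:, 1] * e[:, 0]
    dot = (e_prev * e).sum(axis=1)
    return np.arctan2(cross, dot)


def turning_angle(chain: EpithelialChain, i: int) -> float:
    """psi_i for a single vertex."""
    return float(turning_angles(chain.vertices)[i])


def edge_normals(vertices: NDArray) -> NDArray:
    """Unit normals to each edge e_i, oriented outward from the interior."""
    e = edges(vertices)
    length = np.hypot(e[:, 0], e[:, 1])
    if np.any(length == 0):
        raise DegenerateChainError("zero-length edge")
    # For a CCW loop the outward normal of (dx, dy) is (dy, -dx).
    n = np.column_stack([e[:, 1], -e[:, 0]]) / length[:, None]
    if signed_area(vertices) < 0:
        n = -n
    return n


def edge_normal(chain: EpithelialChain, i: int) -> NDArray:
    """Outward unit normal of edge (x_i, x_{i+1})."""
    return edge_normals(chain.vertices)[i]


def bending_forces(vertices: NDArray, k_b: float) -> NDArray:
    """Bending force at every vertex; zero when neighboring psi are equal."""
    psi = turning_angles(vertices)
    n = edge_normals(vertices)
    ell = edge_lengths(vertices)
    psi_prev = np.roll(psi, 1)
    psi_next = np.roll(psi, -1)
    n_prev = np.roll(n, 1, axis=0)  # normal of edge (x_{i-1}, x_i)
    len_prev = np.roll(ell, 1)  # |x_i - x_{i-1}|
    term1 = ((psi_prev - psi) / len_prev)[:, None] * n_prev
    term2 = ((psi_next - psi) / ell)[:, None] * n
    return k_b * (term1 + term2)


def tension_forces(vertices: NDArray, k_s: float, l0: float) -> NDArray:
    """Restoring spring force at every vertex for both adjacent edges."""
    e = edges(vertices)
    ell = edge_lengths(vertices)
    if np.any(ell == 0):
        raise DegenerateChainError("zero-length edge")
    unit = e / ell[:, None]
    stretch = ell - l0
    # edge i acts on vertex i toward x_{i+1}, and on vertex i+1 toward x_i
    pull_fwd = (stretch[:, None] * unit)  # on vertex i
    pull_back = -np.roll(stretch[:, None] * unit, 1, axis=0)  # on vertex i
    return k_s * (pull_fwd + pull_back)


def pressure_forces(vertices: NDArray, k_p: float) -> NDArray:
    """Luminal pressure k_p (n_{i-1} + n_i) at every vertex, outward."""
    n = edge_normals(vertices)
    return k_p * (n + np.roll(n, 1, axis=0))


def bending_force(chain: EpithelialChain, i: int, k_b: float) -> NDArray:
    return bending_forces(chain.vertices, k_b)[i]


def tension_force(chain: EpithelialChain, i: int, k_s: float) -> NDArray:
    return tension_forces(chain.vertices, k_s, chain.l0)[i]


def pressure_force(chain: EpithelialChain, i: int, k_p: float) -> NDArray:
    return pressure_forces(chain.vertices, k_p)[i]


def internal_forces(chain: EpithelialChain, k_b: float, k_s: float, k_p: float) -> NDArray:
    """F_b + F_t + F_p at every vertex of the chain."""
    v = chain.vertices
    return (
        bending_forces(v, k_b)
        + tension_forces(v, k_s, chain.l0)
        + pressure_forces(v, k_p)
    )


def epithelial_velocity(
    chain: EpithelialChain,
    i: int,
    F_interaction: ArrayLike,
    params,
) -> NDArray:
    """Overdamped vertex velocity gamma_e * (F_b + F_t + F_p + F_i)."""
    internal = internal_forces(chain, params.k_b, params.k_s, params.k_p)[i]
    return params.gamma_e * (internal + np.asarray(F_interaction, dtype=float))


def regular_polygon(center: ArrayLike, radius: float, n: int, chain_id: int = 0) -> EpithelialChain:
    """Regular n-gon chain (CCW); l0 set to the edge length."""
    center = np.asarray(center, dtype=float)
    ang = 2 * np.pi * np.arange(n) / n
    verts = center + radius * np.column_stack([np.cos(ang), np.sin(ang)])
    l0 = 2 * radius * np.sin(np.pi / n)
    return EpithelialChain(chain_id, verts, l0)


def capsule(
    center: ArrayLike,
    length: float,
    width: float,
    n: int,
    chain_id: int = 0,
    axis: str = "y",
) -> EpithelialChain:
    """Capsule-shaped closed loop: two straight runs joined by semicircles.

    ``length`` is the straight-run extent along the long axis, ``width``
    the full breadth (cap diameter). Vertices are spaced uniformly in
    arclength; l0 is the mean edge length.
    """
    if width <= 0 or length < 0:
        raise ValueError("capsule needs width > 0 and length >= 0")
    r = width / 2.0
    per = 2 * length + 2 * np.pi * r
    s = per * np.arange(n) / n
    pts = np.empty((n, 2))
    for k, sk in enumerate(s):
        if sk < length:  # right wall, going up
            pts[k] = (r, sk - length / 2)
        elif sk < length + np.pi * r:  # top cap
            a = (sk - length) / r
            pts[k] = (r * np.cos(a), length / 2 + r * np.sin(a))
        elif sk < 2 * length + np.pi * r:  # left wall, going down
            pts[k] = (-r, length / 2 - (sk - length - np.pi * r))
        else:  # bottom cap
            a = (sk - 2 * length - np.pi * r) / r
            pts[k] = (-r * np.cos(a), -length / 2 - r * np.sin(a))
    if axis == "x":
        pts = pts[:, ::-1].copy()
        pts[:, 1] = -pts[:, 1]  # keep CCW orientation
    center = np.asarray(center, dtype=float)
    verts = pts + center
    l0 = float(np.mean(edge_lengths(verts)))
    return EpithelialChain(chain_id, verts, l0)
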