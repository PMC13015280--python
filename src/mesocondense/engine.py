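"""Seeded time integration: initialization, stepping, proliferation, recording.

Explicit Euler with synchronous force evaluation: all forces are computed
from the positions at the start of the step, then every agent moves at
once. Reflecting boundaries keep agents in [0, L]^2. Per-agent repulsion
uses a KD-tree neighbor query whose output is tested against a direct
all-pairs sum.

Randomness comes from three independent streams spawned from the master
seed (initialization, motion noise, proliferation placement), so turning
proliferation on or off does not perturb the motion noise sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import NDArray
from scipy.spatial import cKDTree

from . import chains as chainmod
from . import forces
from .chains import EpithelialChain, capsule, regular_polygon
from .forces import COINCIDENCE_JITTER, repulsion_magnitude, wrap_angle
from .params import MorphogenSource, SimulationParams

log = logging.getLogger(__name__)


class InitializationError(RuntimeError):
    """Requested initial packing could not be achieved."""


class NumericalInstabilityError(RuntimeError):
    """An agent position became non-finite during integration."""


@dataclass(frozen=True)
class MesenchymalCell:
    """Read-only view of one mesenchymal agent."""

    id: int
    position: NDArray
    theta: float
    birth_step: int  # -1 for founders


@dataclass
class SimulationState:
    """All agents at one time step (array-of-struct layout for speed)."""

    step: int
    positions: NDArray  # (N, 2) mesenchymal positions
    thetas: NDArray  # (N,) polarity angles
    ids: NDArray  # (N,) unique integer ids
    birth_steps: NDArray  # (N,) birth step, -1 for founders
    chains: list[EpithelialChain] = field(default_factory=list)
    source: MorphogenSource | None = None
    next_id: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def cells(self) -> list[MesenchymalCell]:
        return [
            MesenchymalCell(int(i), x.copy(), float(t), int(b))
            for i, x, t, b in zip(self.ids, self.positions, self.thetas, self.birth_steps)
        ]

    def copy(self) -> "SimulationState":
        return SimulationState(
            step=self.step,
            positions=self.positions.copy(),
            thetas=self.thetas.copy(),
            ids=self.ids.copy(),
            birth_steps=self.birth_steps.copy(),
            chains=[c.copy() for c in self.chains],
            source=self.source,
            next_id=self.next_id,
        )


@dataclass
class Trajectory:
    """Time-ordered snapshots plus the proliferation event log."""

    params: SimulationParams
    snapshots: list[SimulationState]
    events: list[dict[str, Any]] = field(default_factory=list)

    @property
    def final(self) -> SimulationState:
        return self.snapshots[-1]

    def snapshot_steps(self) -> list[int]:
        return [s.step for s in self.snapshots]


@dataclass
class Streams:
    """The three independent RNG streams of a run."""

    init: np.random.Generator
    motion: np.random.Generator
    prolif: np.random.Generator
    stability_warned: bool = False  # one dt warning per run

    @classmethod
    def from_seed(cls, seed: int) -> "Streams":
        ss = np.random.SeedSequence(seed)
        g = [np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(3)]
        return cls(*g)


def reflect(position: NDArray, box_length: float) -> NDArray:
    """Mirror coordinates at 0 and box_length into the domain.

    Implemented as a triangular fold (repeated mirroring), so it is
    correct for displacements of any magnitude; in-domain input is
    returned unchanged.
    """
    pos = np.mod(np.asarray(position, dtype=float), 2 * box_length)
    over = pos > box_length
    pos[over] = 2 * box_length - pos[over]
    return pos


def _point_in_any_chain(pts: NDArray, chains: list[EpithelialChain]) -> NDArray:
    """Boolean mask of points inside any chain interior (ray crossing)."""
    inside = np.zeros(len(pts), dtype=bool)
    for ch in chains:
        v = ch.vertices
        x1, y1 = v[:, 0], v[:, 1]
        x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
        for k, (px, py) in enumerate(pts):
            cond = (y1 > py) != (y2 > py)
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            crossings = np.count_nonzero(cond & (px < xint))
            if crossings % 2 == 1:
                inside[k] = True
    return inside


def initialize_state(
    params: SimulationParams,
    n_cells: int,
    source: MorphogenSource | None = None,
    chains: list[EpithelialChain] | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = 200,
) -> SimulationState:
    """Uniformly random mesenchyme outside the bead disk and chain interiors.

    Polarity angles are uniform on (-pi, pi]. Chains are taken as given
    (use :func:`mesocondense.chains.regular_polygon` / :func:`capsule`).
    """
    if rng is None:
        rng = Streams.from_seed(params.seed).init
    chains = [c.copy() for c in (chains or [])]
    L = params.box_length
    placed = np.empty((0, 2))
    for _ in range(max_attempts):
        need = n_cells - len(placed)
        if need <= 0:
            break
        cand = rng.uniform(0.0, L, size=(max(need, 1), 2))
        ok = np.ones(len(cand), dtype=bool)
        if source is not None and source.bead_radius > 0:
            d = np.hypot(cand[:, 0] - source.center[0], cand[:, 1] - source.center[1])
            ok &= d > source.bead_radius
        if chains:
            ok &= ~_point_in_any_chain(cand, chains)
        placed = np.vstack([placed, cand[ok]])
    if len(placed) < n_cells:
        raise InitializationError(
            f"could not place {n_cells} cells outside exclusion zones"
        )
    placed = placed[:n_cells]
    thetas = wrap_angle(rng.uniform(-np.pi, np.pi, size=n_cells))
    return SimulationState(
        step=0,
        positions=placed,
        thetas=thetas,
        ids=np.arange(n_cells, dtype=np.int64),
        birth_steps=np.full(n_cells, -1, dtype=np.int64),
        chains=chains,
        source=source,
        next_id=n_cells,
    )


def _chain_slices(state: SimulationState, offset: int) -> list[tuple[int, int]]:
    out = []
    for ch in state.chains:
        out.append((offset, offset + ch.n))
        offset += ch.n
    return out


def _all_positions(state: SimulationState) -> tuple[NDArray, list[tuple[int, int]]]:
    """Stacked mesenchymal + chain-vertex positions and per-chain slices."""
    blocks = [state.positions] + [c.vertices for c in state.chains]
    stacked = np.vstack(blocks) if blocks else np.empty((0, 2))
    return stacked, _chain_slices(state, len(state.positions))


def interaction_forces(
    state: SimulationState, params: SimulationParams, rng: np.random.Generator
) -> NDArray:
    """Net repulsion on every agent (mesenchyme then chain vertices, stacked).

    One global kernel for all pairs — mesenchyme-mesenchyme, cross-type,
    and non-adjacent epithelium-epithelium; adjacent chain vertices are
    bonded, not repelling. Coincident pairs are resolved by a seeded
    jitter of 1e-6 * d_c before the force evaluation. The bead obstacle
    repels every agent from its nearest surface point.
    """
    pos, chain_slices = _all_positions(state)
    n = len(pos)
    F = np.zeros((n, 2))
    if n == 0:
        return F
    d_c = params.d_c
    for _ in range(3):  # de-duplicate coincident agents, then recompute
        tree = cKDTree(pos)
        pairs = tree.query_pairs(d_c, output_type="ndarray")
        if len(pairs) == 0:
            break
        i, j = pairs[:, 0], pairs[:, 1]
        dx = pos[i] - pos[j]
        r = np.hypot(dx[:, 0], dx[:, 1])
        if not np.any(r == 0.0):
            break
        bad = np.unique(j[r == 0.0])
        pos = pos.copy()
        pos[bad] += rng.normal(scale=COINCIDENCE_JITTER * d_c, size=(len(bad), 2))
    if len(pairs) > 0:
        # drop bonded (adjacent within one chain) pairs; query_pairs gives i < j
        keep = np.ones(len(i), dtype=bool)
        for lo, hi in chain_slices:
            in_chain = (i >= lo) & (j < hi)
            nvert = hi - lo
            adjacent = in_chain & (
                (j - i == 1) | ((i == lo) & (j == hi - 1) & (nvert > 2))
            )
            keep &= ~adjacent
        i, j, dx, r = i[keep], j[keep], dx[keep], r[keep]
        mag = repulsion_magnitude(r, params.k_rep, d_c, params.lam)
        fvec = (mag / r)[:, None] * dx
        # accumulate each row's contributions in ascending neighbor order so
        # the result is bit-identical to a direct ordered all-pairs sum
        di = np.concatenate([i, j])
        dj = np.concatenate([j, i])
        dF = np.concatenate([fvec, -fvec])
        order = np.lexsort((dj, di))
        np.add.at(F, di[order], dF[order])
    if state.source is not None and state.source.bead_radius > 0:
        F += forces.bead_repulsion_many(pos, state.source, params)
    return F


def count_in_region(state: SimulationState) -> int:
    """Mesenchymal cells with distance to the source center below R."""
    if state.source is None or state.n_cells == 0:
        return 0
    cx, cy = state.source.center
    d = np.hypot(state.positions[:, 0] - cx, state.positions[:, 1] - cy)
    return int(np.count_nonzero(d < state.source.region_radius))


def proliferate(
    state: SimulationState, params: SimulationParams, rng: np.random.Generator
) -> int:
    """Add floor(p * N_region) daughters near random in-region mothers.

    Each daughter is the jitter of a uniformly chosen mother by an offset
    of magnitude <= d_c / 2, reflected back into the domain and pushed
    outside the bead disk. Mutates ``state`` in place; returns the number
    of cells added.
    """
    if state.source is None or params.p <= 0:
        return 0
    cx, cy = state.source.center
    d = np.hypot(state.positions[:, 0] - cx, state.positions[:, 1] - cy)
    in_region = np.flatnonzero(d < state.source.region_radius)
    n_add = int(np.floor(params.p * len(in_region)))
    if n_add == 0:
        return 0
    mothers = rng.choice(in_region, size=n_add, replace=True)
    ang = rng.uniform(-np.pi, np.pi, size=n_add)
    mag = rng.uniform(0.0, params.d_c / 2, size=n_add)
    offs = mag[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
    new_pos = reflect(state.positions[mothers] + offs, params.box_length)
    if state.source.bead_radius > 0:
        dd = np.hypot(new_pos[:, 0] - cx, new_pos[:, 1] - cy)
        inside = dd < state.source.bead_radius
        if np.any(inside):
            # push radially just outside the bead surface
            safe = np.where(dd[inside] > 0, dd[inside], 1.0)
            ux = (new_pos[inside, 0] - cx) / safe
            uy = (new_pos[inside, 1] - cy) / safe
            rr = state.source.bead_radius * (1 + COINCIDENCE_JITTER)
            new_pos[inside, 0] = cx + rr * ux
            new_pos[inside, 1] = cy + rr * uy
            new_pos[inside] = reflect(new_pos[inside], params.box_length)
    new_thetas = wrap_angle(rng.uniform(-np.pi, np.pi, size=n_add))
    new_ids = np.arange(state.next_id, state.next_id + n_add, dtype=np.int64)
    state.positions = np.vstack([state.positions, new_pos])
    state.thetas = np.concatenate([state.thetas, new_thetas])
    state.ids = np.concatenate([state.ids, new_ids])
    state.birth_steps = np.concatenate(
        [state.birth_steps, np.full(n_add, state.step, dtype=np.int64)]
    )
    state.next_id += n_add
    return n_add


def step(
    state: SimulationState,
    params: SimulationParams,
    streams: Streams,
    events: list[dict[str, Any]] | None = None,
) -> SimulationState:
    """Advance one explicit-Euler step (synchronous update).

    Order: forces from start-of-step positions -> move all agents ->
    reflect -> polarity update (chemotaxis + rotational noise) ->
    proliferation when the new step index is a multiple of
    ``prolif_interval``.
    """
    state = state.copy()
    n_m = state.n_cells
    F = interaction_forces(state, params, streams.motion)
    # mesenchymal update
    if n_m:
        ni = np.column_stack([np.cos(state.thetas), np.sin(state.thetas)])
        vel = params.gamma_m * (params.v0 * ni + F[:n_m])
        disp = params.dt * vel
        max_disp = float(np.max(np.hypot(disp[:, 0], disp[:, 1])))
        if max_disp > params.d_c and not streams.stability_warned:
            # warn once per run; overlapping random initial placements make
            # a large-force transient in the first few steps normal
            streams.stability_warned = True
            log.warning(
                "step %d: max displacement %.3g exceeds d_c=%.3g; "
                "reduce dt if this persists beyond the initial steps",
                state.step + 1, max_disp, params.d_c,
            )
        state.positions = reflect(state.positions + disp, params.box_length)
    # epithelial update
    off = n_m
    for ch in state.chains:
        internal = chainmod.internal_forces(ch, params.k_b, params.k_s, params.k_p)
        vel = params.gamma_e * (internal + F[off : off + ch.n])
        ch.vertices = reflect(ch.vertices + params.dt * vel, params.box_length)
        off += ch.n
    if n_m:
        noise = (
            np.sqrt(2 * params.D_theta * params.dt)
            * streams.motion.standard_normal(n_m)
            if params.D_theta > 0
            else 0.0
        )
        state.thetas = forces.polarity_update_many(
            state.thetas, state.positions, state.source, params.alpha, noise
        )
    bad = ~np.isfinite(state.positions).all(axis=1)
    if np.any(bad):
        raise NumericalInstabilityError(
            f"non-finite position for cell id {int(state.ids[np.argmax(bad)])} "
            f"at step {state.step + 1}; reduce dt"
        )
    for ch in state.chains:
        if not np.isfinite(ch.vertices).all():
            raise NumericalInstabilityError(
                f"non-finite vertex in chain {ch.id} at step {state.step + 1}; reduce dt"
            )
    state.step += 1
    if params.p > 0 and state.source is not None and (
        state.step % params.prolif_interval == 0
    ):
        n_region = count_in_region(state)
        added = proliferate(state, params, streams.prolif)
        if added and events is not None:
            events.append(
                {
                    "step": state.step,
                    "kind": "proliferation",
                    "n_region": n_region,
                    "added": added,
                }
            )
    return state


def run(
    params: SimulationParams,
    n_cells: int,
    source: MorphogenSource | None = None,
    chains: list[EpithelialChain] | None = None,
    snapshot_stride: int = 100,
) -> Trajectory:
    """Initialize and integrate ``params.n_steps`` steps.

    Snapshots are recorded at step 0, every ``snapshot_stride`` steps,
    and at the final step. Identical params and seed reproduce the
    trajectory bit-for-bit.
    """
    streams = Streams.from_seed(params.seed)
    state = initialize_state(params, n_cells, source, chains, rng=streams.init)
    events: list[dict[str, Any]] = []
    snaps = [state.copy()]
    for _ in range(params.n_steps):
        state = step(state, params, streams, events)
        if state.step % snapshot_stride == 0 or state.step == params.n_steps:
            snaps.append(state.copy())
    if snaps[-1].step != state.step:
        snaps.append(state.copy())
    return Trajectory(params=params, snapshots=snaps, events=events)
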