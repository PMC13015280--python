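"""The two in-silico experiments, packaged as one-call seeded pipelines.

* :func:`scenario_condensation` — a morphogen source (bead) at the box
  center with free mesenchyme; enhanced proliferation, directed
  migration, both, or neither. Summarized by the condensation index:
  the area-normalized cell density within the source-adjacent region
  divided by the far-field density.
* :func:`scenario_two_branches` — the source between two capsule-shaped
  epithelial branches; with migration off the inflating branches close
  on the bead, with migration on a mesenchymal condensation forms and
  holds the epithelium away. Summarized by the bead-branch distance
  over time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import metrics
from .chains import capsule
from .engine import SimulationState, Trajectory, run
from .params import MorphogenSource, SimulationParams

MODES = ("none", "proliferation", "migration", "both")


@dataclass
class ScenarioSummary:
    """Headline quantities of a scenario run."""

    mode: str
    condensation_index: float  # nan when undefined (e.g. no cells)
    final_cell_count: int
    bead_branch_distance_series: list[tuple[int, float]] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return math.isnan(self.condensation_index)


def _mode_params(params: SimulationParams, mode: str) -> SimulationParams:
    """Zero out alpha and/or p according to the scenario mode."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    alpha = params.alpha if mode in ("migration", "both") else 0.0
    p = params.p if mode in ("proliferation", "both") else 0.0
    return params.model_copy(update={"alpha": alpha, "p": p})


def condensation_index(state: SimulationState, box_length: float) -> float:
    """Near-source / far-field density ratio of the mesenchyme.

    The bead disk is excluded from the region area (cells cannot occupy
    it); the outside area is the rest of the box.
    """
    src = state.source
    if src is None or state.n_cells == 0:
        return float("nan")
    L = box_length
    call = metrics.detect_condensation(
        state.positions,
        src.center,
        src.region_radius,
        threshold_ratio=1.5,
        domain_area=L * L,
        excluded_area=np.pi * src.bead_radius**2,
    )
    return call.index


def scenario_condensation(
    mode: str,
    params: SimulationParams | None = None,
    n_cells: int = 800,
    bead_radius: float = 0.5,
    snapshot_stride: int = 250,
) -> tuple[Trajectory, ScenarioSummary]:
    """Bead at the box center, free mesenchyme, no epithelium.

    ``mode`` selects which TGF-beta responses are active: ``none``,
    ``proliferation`` (p > 0), ``migration`` (alpha > 0), or ``both``.
    """
    params = params or SimulationParams()
    params = _mode_params(params, mode)
    c = params.box_length / 2
    source = MorphogenSource((c, c), bead_radius=bead_radius, region_radius=params.R)
    traj = run(params, n_cells=n_cells, source=source, snapshot_stride=snapshot_stride)
    final = traj.final
    summary = ScenarioSummary(
        mode=mode,
        condensation_index=condensation_index(final, params.box_length),
        final_cell_count=final.n_cells,
    )
    return traj, summary


def two_branch_chains(
    params: SimulationParams,
    branch_offset: float = 3.5,
    branch_length: float = 8.0,
    branch_width: float = 2.4,
    n_vertices: int = 64,
):
    """Two vertical capsule loops flanking the box center."""
    c = params.box_length / 2
    left = capsule((c - branch_offset, c), branch_length, branch_width, n_vertices, chain_id=0)
    right = capsule((c + branch_offset, c), branch_length, branch_width, n_vertices, chain_id=1)
    return [left, right]


def bead_branch_series(traj: Trajectory) -> list[tuple[int, float]]:
    """Minimum bead-surface-to-branch distance at every snapshot."""
    out = []
    for snap in traj.snapshots:
        if snap.source is None or not snap.chains:
            continue
        d = min(
            metrics.bead_branch_distance(
                snap.source, metrics.Polyline(ch.vertices, closed=True)
            )
            for ch in snap.chains
        )
        out.append((snap.step, d))
    return out


def scenario_two_branches(
    migration_on: bool,
    params: SimulationParams | None = None,
    n_cells: int = 800,
    bead_radius: float = 0.5,
    snapshot_stride: int = 250,
    **geometry,
) -> tuple[Trajectory, ScenarioSummary]:
    """Morphogen source between two epithelial branches.

    With ``migration_on=False`` (vehicle-control bead) luminal pressure
    lets the branches expand toward the bead; with ``migration_on=True``
    the condensing mesenchyme deforms the epithelium around itself and
    keeps the branches at bay.
    """
    params = params or SimulationParams()
    params = _mode_params(params, "migration" if migration_on else "none")
    c = params.box_length / 2
    source = MorphogenSource((c, c), bead_radius=bead_radius, region_radius=params.R)
    chains = two_branch_chains(params, **geometry)
    traj = run(
        params,
        n_cells=n_cells,
        source=source,
        chains=chains,
        snapshot_stride=snapshot_stride,
    )
    series = bead_branch_series(traj)
    summary = ScenarioSummary(
        mode="migration" if migration_on else "none",
        condensation_index=condensation_index(traj.final, params.box_length),
        final_cell_count=traj.final.n_cells,
        bead_branch_distance_series=series,
    )
    return traj, summary
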