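"""Trajectory and point/polyline file formats.

Trajectories are TSV: ``#``-prefixed JSON header lines echoing the
parameters, then a header row and one row per agent per snapshot
(step, agent_type {M, E}, agent_id, chain_id, x, y, theta, birth_step).
Floats are written with ``repr`` so a round trip is lossless at full
double precision. Proliferation events go to a JSON-lines sidecar
``<path>.events.jsonl``. Plain text is deliberate: transparent and
diff-able at desk scale, unsuitable for very large runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chains import EpithelialChain
from .engine import SimulationState, Trajectory
from .metrics import PointSet, Polyline
from .params import MorphogenSource, SimulationParams

COLUMNS = ["step", "agent_type", "agent_id", "chain_id", "x", "y", "theta", "birth_step"]


def _f(x: float) -> str:
    return repr(float(x))


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    header = {"params": traj.params.model_dump()}
    if traj.snapshots and traj.snapshots[0].source is not None:
        s = traj.snapshots[0].source
        header["source"] = {
            "center": list(s.center),
            "bead_radius": s.bead_radius,
            "region_radius": s.region_radius,
        }
    header["chain_l0"] = {str(c.id): c.l0 for c in traj.snapshots[0].chains} if traj.snapshots else {}
    lines.append("# " + json.dumps(header))
    lines.append("\t".join(COLUMNS))
    for snap in traj.snapshots:
        for i in range(snap.n_cells):
            lines.append(
                "\t".join(
                    [
                        str(snap.step),
                        "M",
                        str(int(snap.ids[i])),
                        "",
                        _f(snap.positions[i, 0]),
                        _f(snap.positions[i, 1]),
                        _f(snap.thetas[i]),
                        str(int(snap.birth_steps[i])),
                    ]
                )
            )
        for ch in snap.chains:
            for k, (x, y) in enumerate(ch.vertices):
                lines.append(
                    "\t".join(
                        [str(snap.step), "E", str(k), str(ch.id), _f(x), _f(y), "", ""]
                    )
                )
    path.write_text("\n".join(lines) + "\n")
    events_path = path.with_suffix(path.suffix + ".events.jsonl")
    events_path.write_text("".join(json.dumps(e) + "\n" for e in traj.events))
    return path


class TrajectoryParseError(ValueError):
    pass


def read_trajectory(path: str | Path) -> Trajectory:
    """Inverse of :func:`write_trajectory`; lossless round trip."""
    path = Path(path)
    header: dict = {}
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.startswith("#"):
                header.update(json.loads(line[1:]))
            else:
                break
    try:
        params = SimulationParams.model_validate(header["params"])
    except KeyError as err:
        raise TrajectoryParseError(f"{path}: missing params header") from err
    source = None
    if "source" in header:
        s = header["source"]
        source = MorphogenSource(tuple(s["center"]), s["bead_radius"], s["region_radius"])
    chain_l0 = {int(k): v for k, v in header.get("chain_l0", {}).items()}
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"agent_type": str, "chain_id": "Int64", "agent_id": "Int64"},
        float_precision="round_trip",
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")
    m_bad = df[(df.agent_type == "M") & df.theta.isna()]
    if len(m_bad):
        raise TrajectoryParseError(
            f"{path}: mesenchymal row without theta near data row {int(m_bad.index[0]) + 1}"
        )
    snaps = []
    for step_val, grp in df.groupby("step", sort=True):
        m = grp[grp.agent_type == "M"]
        chains = []
        for cid, cgrp in grp[grp.agent_type == "E"].groupby("chain_id"):
            cgrp = cgrp.sort_values("agent_id")
            chains.append(
                EpithelialChain(
                    int(cid),
                    cgrp[["x", "y"]].to_numpy(float),
                    chain_l0.get(int(cid), 1.0),
                )
            )
        ids = m.agent_id.to_numpy(np.int64) if len(m) else np.empty(0, np.int64)
        snaps.append(
            SimulationState(
                step=int(step_val),
                positions=m[["x", "y"]].to_numpy(float),
                thetas=m.theta.to_numpy(float) if len(m) else np.empty(0),
                ids=ids,
                birth_steps=m.birth_step.to_numpy(np.int64) if len(m) else np.empty(0, np.int64),
                chains=chains,
                source=source,
                next_id=int(ids.max()) + 1 if len(ids) else 0,
            )
        )
    events_path = path.with_suffix(path.suffix + ".events.jsonl")
    events = []
    if events_path.exists():
        for line in events_path.read_text().splitlines():
            if line.strip():
                events.append(json.loads(line))
    return Trajectory(params=params, snapshots=snaps, events=events)


def write_points(ps: PointSet, path: str | Path) -> Path:
    """Point set as CSV with header x,y[,label]."""
    path = Path(path)
    cols = {"x": ps.points[:, 0], "y": ps.points[:, 1]}
    if ps.labels is not None:
        cols["label"] = ps.labels
    pd.DataFrame(cols).to_csv(path, index=False)
    return path


def read_points(path: str | Path, units: str = "dimensionless") -> PointSet:
    df = pd.read_csv(path)
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return PointSet(df[["x", "y"]].to_numpy(float), labels=labels, units=units)


def write_polyline(poly: Polyline, path: str | Path) -> Path:
    """Polyline as CSV plus a JSON metadata sidecar (closed, tip, units)."""
    path = Path(path)
    pd.DataFrame({"x": poly.vertices[:, 0], "y": poly.vertices[:, 1]}).to_csv(
        path, index=False
    )
    meta = {"closed": poly.closed, "tip_index": poly.tip_index, "units": poly.units}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    return path


def read_polyline(path: str | Path) -> Polyline:
    path = Path(path)
    df = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Polyline(
        df[["x", "y"]].to_numpy(float),
        closed=bool(meta.get("closed", False)),
        tip_index=meta.get("tip_index"),
        units=meta.get("units", "dimensionless"),
    )
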