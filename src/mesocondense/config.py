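"""Run configuration: schema-validated parameters plus scenario selection.

Config files are YAML (JSON is a YAML subset, so both parse). Unknown
keys are rejected with the offending key named; missing keys take the
documented defaults, and the full effective configuration is echoed
into every output header so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .params import SimulationParams


class ChainSpec(BaseModel):
    """Initial geometry of one epithelial chain."""

    model_config = ConfigDict(extra="forbid")

    shape: Literal["polygon", "capsule"] = "polygon"
    center: tuple[float, float] = (10.0, 10.0)
    radius: float = 3.0  # polygon circumradius
    length: float = 8.0  # capsule straight-run extent
    width: float = 2.4  # capsule breadth
    n_vertices: int = Field(default=32, ge=4)
    axis: Literal["x", "y"] = "y"


class RunConfig(BaseModel):
    """Everything needed to reproduce a simulation run."""

    model_config = ConfigDict(extra="forbid")

    params: SimulationParams = Field(default_factory=SimulationParams)
    scenario: Literal["free", "condensation", "two_branches"] = "free"
    mode: Literal["none", "proliferation", "migration", "both"] = "none"
    n_cells: int = Field(default=800, ge=0)
    bead_radius: float = Field(default=0.5, ge=0)
    source: bool = True
    chains: list[ChainSpec] = Field(default_factory=list)
    snapshot_stride: int = Field(default=250, ge=1)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a config file; empty file means all defaults.

    Flat simulation-parameter keys (e.g. ``d_c``, ``lam``) may appear at
    the top level and are folded into ``params`` for convenience.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    if overrides:
        raw = {**raw, **overrides}
    param_keys = set(SimulationParams.model_fields)
    flat = {k: raw.pop(k) for k in list(raw) if k in param_keys}
    if flat:
        raw["params"] = {**raw.get("params", {}), **flat}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        raise ValueError(f"invalid configuration: {err}") from err
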