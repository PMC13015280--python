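"""Model parameters and the morphogen source.

All quantities are dimensionless: the simulation domain is a 20 x 20 box
and the repulsion cutoff ``d_c = 0.6`` sets the cell-size scale, so one
model length unit corresponds to roughly one cell diameter / 0.6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field, model_validator


class SimulationParams(BaseModel):
    """Every constant of the agent-based model.

    Mesenchymal cells are overdamped self-propelled particles,

        dx_i/dt = gamma_m * (v0 * n_i + F_i),    n_i = (cos theta_i, sin theta_i),

    with short-range pairwise repulsion below the cutoff ``d_c`` and
    rotational noise on the polarity angle (Brownian motion by default).
    Epithelial branches are closed vertex chains moved by bending, tension,
    luminal pressure and interaction forces,

        dx_i/dt = gamma_e * (F_b + F_t + F_p + F_i).

    Parameters
    ----------
    box_length : float
        Side of the square domain with reflecting boundaries.
    dt : float
        Explicit-Euler time step. The default keeps the per-step
        displacement well below ``d_c``.
    n_steps : int
        Number of integration steps for :func:`mesocondense.engine.run`.
    gamma_m, gamma_e : float
        Motility (inverse friction) coefficients of mesenchymal cells and
        epithelial vertices.
    v0 : float
        Self-propulsion speed of mesenchymal cells.
    k_rep : float
        Repulsion strength, one global value for every agent pair.
    d_c : float
        Repulsion cutoff distance; pairs farther apart do not interact.
    lam : float
        Repulsion exponent (stiffness of the contact divergence).
    alpha : float
        Chemotactic strength: polarity turn rate toward the source inside
        the source-adjacent region. Applied once per step, not scaled by
        ``dt``; rescale ``alpha`` if you change ``dt``.
    R : float
        Radius of the source-adjacent region in which chemotactic
        alignment and proliferation act.
    p : float
        Proliferation coefficient in [0, 1): every ``prolif_interval``
        steps, ``floor(p * N_region)`` daughters are added inside the
        region. 0 disables proliferation.
    k_b, k_s, k_p : float
        Bending, tension and luminal-pressure coefficients of the
        epithelial chain.
    D_theta : float
        Rotational diffusion coefficient; the polarity angle receives
        Gaussian noise of std ``sqrt(2 * D_theta * dt)`` each step.
    prolif_interval : int
        Steps between proliferation events.
    seed : int
        Master seed; independent streams are spawned for initialization,
        motion noise and proliferation placement.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    box_length: float = Field(default=20.0, gt=0)
    dt: float = Field(default=0.01, ge=0)
    n_steps: int = Field(default=5000, ge=0)
    gamma_m: float = Field(default=1.0, ge=0)
    gamma_e: float = Field(default=1.0, ge=0)
    v0: float = Field(default=0.4, ge=0)
    k_rep: float = Field(default=1.0, ge=0)
    d_c: float = Field(default=0.6, gt=0)
    lam: float = Field(default=2.0, gt=0)
    alpha: float = Field(default=0.3, ge=0)
    R: float = Field(default=3.0, gt=0)
    p: float = Field(default=0.02, ge=0, lt=1)
    k_b: float = Field(default=0.5, ge=0)
    k_s: float = Field(default=2.0, ge=0)
    k_p: float = Field(default=0.3, ge=0)
    D_theta: float = Field(default=0.25, ge=0)
    prolif_interval: int = Field(default=50, ge=1)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_dt_stability_scale(self) -> "SimulationParams":
        if self.dt > 0 and self.v0 * self.gamma_m * self.dt > self.box_length:
            raise ValueError("per-step free displacement exceeds the box size")
        return self


@dataclass(frozen=True)
class MorphogenSource:
    """Circular morphogen source (a TGF-beta-soaked bead in the experiments).

    ``bead_radius`` is an exclusion disk: agents are repelled from the
    nearest point of the bead surface with the same kernel as cell-cell
    repulsion. ``bead_radius = 0`` is a point source. ``region_radius`` is
    the source-adjacent region R within which chemotaxis and proliferation
    apply.
    """

    center: tuple[float, float]
    bead_radius: float = 0.0
    region_radius: float = 3.0

    def __post_init__(self) -> None:
        if not self.bead_radius >= 0:
            raise ValueError("bead_radius must be >= 0")
        if not self.region_radius > self.bead_radius:
            raise ValueError("region_radius must exceed bead_radius")
        if not all(math.isfinite(c) for c in self.center):
            raise ValueError("source center must be finite")
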