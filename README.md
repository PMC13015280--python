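# mesocondense

An off-lattice, two-dimensional agent-based model of how mesenchymal
cells condense around a localized morphogen source (a TGF-β-releasing
bead in embryonic lung mesenchyme) and how the resulting cell mass
mechanically displaces neighboring epithelial branches — together with
the spatial metrics used to quantify condensation and branch spacing on
point sets and outlines.

It is aimed at people studying branching morphogenesis who want to ask
*which cell behavior produces a condensation* — enhanced proliferation
or directed migration — and whether mesenchyme–epithelium contact
forces alone can reshape a branch, without fitting to images.

## Model

Mesenchymal cells are overdamped self-propelled point particles,

    dx_i/dt = γ_m (v₀ n_i + F_i),    n_i = (cos θ_i, sin θ_i),

whose polarity angle θ_i diffuses rotationally (Brownian motion by
default) and, inside a region of radius R around the source, turns
toward it by Δθ_i = α(1 − d_i/R) sin(φ_i − θ_i) each step. All agents
repel pairwise below a cutoff d_c = 0.6 with kernel
f(r) = r/λ + (d_c/r)^λ − d_c/λ − 1 (λ = 2). Proliferation adds
⌊p·N_region⌋ daughters inside the region at fixed intervals. Epithelial
branches are closed vertex chains with bending, tension and luminal
pressure forces,

    dx_i/dt = γ_e (F_b + F_t + F_p + F_i),

in a 20 × 20 box with reflecting boundaries. See `docs/methods.md` for
the full force definitions, the parameter table, and the reasoning
behind every default.

## Worked example

Run the bead-condensation experiment in migration-only and
proliferation-only mode:

```python
from mesocondense import SimulationParams, scenario_condensation

for mode in ("proliferation", "migration"):
    _, summary = scenario_condensation(mode, SimulationParams(seed=1))
    print(mode, round(summary.condensation_index, 3), summary.final_cell_count)
```

prints

```
proliferation 1.123 900
migration 2.672 800
```

The condensation index is the cell density inside the source-adjacent
region divided by the far-field density: ≈ 1 means no enrichment. With
directed migration the mesenchyme packs around the bead (index ≈ 2.7);
with enhanced proliferation alone the extra 100 cells disperse and the
density barely rises (index ≈ 1.1, within the fluctuation range of the
null condition) — proliferation does not make a
condensation, migration does.

The two-branch experiment places the source between two epithelial
branches:

```python
from mesocondense import SimulationParams
from mesocondense.scenarios import scenario_two_branches

for migration_on in (False, True):
    _, s = scenario_two_branches(migration_on, SimulationParams(seed=1))
    print(migration_on, round(s.bead_branch_distance_series[-1][1], 3))
```

prints

```
False 0.325
True 1.372
```

Starting from a bead–branch gap of 1.8, the luminal pressure inflates
the branches onto the bead when the mesenchyme is passive (final
distance 0.325), while with directed migration the condensation forms
first and holds the epithelium away (final distance 1.372), deforming
the branch around itself.

The same pipelines are available from the shell:

```sh
mesocondense scenario --mode migration --seed 1 --out out/
mesocondense scenario --two-branches --migration off --seed 1 --out out2/
```

Each invocation writes the trajectory as TSV, a summary JSON and a
manifest sufficient to reproduce the run bit-for-bit. Subcommands
`metrics` and `fixtures` expose the quantification layer (condensation
detection, branch spacing, mark CDFs) and the synthetic ground-truth
generators on CSV files.

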