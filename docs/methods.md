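# Methods

## The model

`mesocondense` simulates the interplay between free mesenchymal cells and
epithelial branches in a two-dimensional tissue slab, driven by a local
morphogen source (experimentally, a TGF-β-soaked bead implanted in
embryonic lung mesenchyme). The question the model addresses is
mechanistic: is a mesenchymal condensation around such a source produced
by enhanced proliferation, by directed migration, or both — and can the
resulting cell mass mechanically displace a neighboring epithelial
branch?

### Mesenchymal cells

Each mesenchymal cell *i* is a point particle with position **x**_i and a
polarity angle θ_i, moving overdamped:

    d**x**_i/dt = γ_m (v₀ **n**_i + **F**_i),   **n**_i = (cos θ_i, sin θ_i)

**F**_i is the sum of pairwise repulsions over all agents within the
cutoff d_c. The repulsion kernel is

    F(r) = k_rep · f(r) · r̂,
    f(r) = r/λ + (d_c/r)^λ − d_c/λ − 1      for 0 < r < d_c, else 0.

f vanishes continuously at r = d_c, decreases strictly on (0, d_c], and
diverges at contact, so cells resist overlap but do not attract. This
algebraic form is a reconstruction: the published description of the
kernel is typographically corrupted, and this is the natural reading
that is continuous at the cutoff, monotone, and divergent at contact.
It is documented here as such rather than asserted as the original
authors' exact expression.

The polarity angle performs rotational diffusion (Gaussian increments of
standard deviation √(2·D_θ·dt) per step), which makes unstimulated cells
Brownian at long times with effective translational diffusivity
D_eff = v₀²/(2 D_θ). Inside the source-adjacent region of radius R the
angle additionally turns toward the source each step:

    Δθ_i = α (1 − d_i/R) sin(φ_i − θ_i)

with d_i the distance to the source center and φ_i the bearing from the
cell to the source. The turn is strongest at the source and fades to
zero at the region boundary. Δθ is applied once per time step, not
scaled by dt; rescale α if you change dt. Proliferation is modeled as a
periodic event (every `prolif_interval` steps): ⌊p·N⌋ daughters are
added, where N is the current number of cells inside the region; each
daughter is placed by jittering a uniformly chosen in-region mother by
at most d_c/2. The floor makes the count deterministic and conservative.

### Epithelial branches

A branch is a closed chain of vertices moved by

    d**x**_i/dt = γ_e (**F**_b + **F**_t + **F**_p + **F**_i)

with bending, tension and luminal-pressure forces:

* **F**_b = k_b [ (ψ_{i−1} − ψ_i)/|x_i − x_{i−1}| **n**_{i−1}
  + (ψ_{i+1} − ψ_i)/|x_{i+1} − x_i| **n**_i ], where ψ_i is the signed
  turning angle between consecutive edges (counter-clockwise positive)
  and **n**_i the outward unit normal of edge (x_i, x_{i+1}). The force
  vanishes wherever neighboring turning angles are equal, i.e. on any
  circular arc, and smooths kinks.
* **F**_t: linear restoring springs on both adjacent edges with a common
  rest length l₀ set at initialization (a stretched edge pulls the
  vertex toward that neighbor, a compressed one pushes it away). The
  restoring sign convention is a deliberate choice — the force must
  maintain cohesion, and a literal reading of the published signs is not
  restoring under symmetric stretch.
* **F**_p = k_p(**n**_{i−1} + **n**_i): luminal pressure, always outward.
  Outwardness is defined via the signed area of the loop, so the force
  inflates the lumen regardless of winding order.

Chain vertices take part in the same repulsion as mesenchymal cells
(one global k_rep for mesenchyme–mesenchyme, mesenchyme–epithelium, and
non-adjacent epithelium–epithelium pairs); bonded neighbors are excluded
since they interact through the springs. The mechanical pathway by which
a condensation displaces a branch is exactly this cross-type repulsion.

### Domain, source, integration

The domain is a 20 × 20 box with reflecting boundaries. The morphogen
source sits at a point with an optional `bead_radius` exclusion disk;
agents are repelled from the nearest point of the bead surface by the
same kernel (radially), so cells condense around, not on, the bead.

Integration is explicit Euler with synchronous force evaluation. The
default dt = 0.01 keeps the free-motion step (γ_m·v₀·dt = 0.004) two
orders of magnitude below d_c. Neighbor search uses a k-d tree
(`scipy.spatial.cKDTree`); per-agent force accumulation runs in
ascending-neighbor order, which makes the assembled forces bit-identical
to a direct ordered all-pairs sum (the test suite verifies this to
1e−12 over random configurations). Coincident agents (r = 0, possible
only at pathological initial conditions) are separated by a seeded
jitter of 10⁻⁶·d_c rather than raising mid-run.

Randomness derives from a single master seed split into three
independent streams — initialization, motion noise, proliferation
placement — so switching proliferation on or off does not perturb the
motion-noise sequence of the other cells. Identical parameters and seed
reproduce trajectories bit-for-bit, and the TSV trajectory format
round-trips at full double precision.

## Parameters and defaults

| name | meaning | default |
|---|---|---|
| box_length | domain side | 20 |
| dt | Euler step | 0.01 |
| n_steps | steps per run | 5000 |
| γ_m, γ_e | motilities | 1 |
| v₀ | self-propulsion speed | 0.4 |
| k_rep | repulsion strength | 1 |
| d_c | repulsion cutoff | 0.6 |
| λ | repulsion exponent | 2 |
| α | chemotactic strength | 0.3 |
| R | source-adjacent radius | 3 |
| p | proliferation coefficient | 0.02 |
| k_b, k_s, k_p | bending, tension, pressure | 0.5, 2, 0.3 |
| D_θ | rotational diffusion | 0.25 |
| prolif_interval | steps between division events | 50 |

Only box size, d_c and λ are published model constants; everything else
is a package default chosen once so that the two scenario experiments
reproduce their qualitative outcomes at the default problem size
(800 cells, 5000 steps):

* With v₀ = 0.4 and D_θ = 0.25 the effective diffusivity is
  D_eff = 0.32, so daughters born inside the region (area ≈ 28 of a
  400-unit² box holding ~56 of the 800 cells initially) disperse over a
  root-mean-square distance comparable to R within the run. That is what
  keeps proliferation-only runs near the uniform baseline (condensation
  index ≈ 1.2 on a 5-seed mean) while migration-only runs condense
  (index ≈ 2.7): slower motility traps daughters in the region and
  produces a spurious proliferation-driven "condensation".
* k_p = 0.3 makes luminal pressure strong enough to inflate the
  branches against the osmotic push of the surrounding mesenchyme (the
  lumen holds no cells, so ambient collisions are purely compressive).
  At the former trial value 0.05 the branches were squeezed away from
  the bead instead of expanding toward it.

All defaults are config-overridable; none were adjusted after freezing.

## Scenarios and summary statistics

**Bead condensation** (`scenario_condensation`): source at the box
center with bead_radius 0.5, no chains, mode ∈ {none, proliferation,
migration, both} gating (α, p). The **condensation index** is the
area-normalized cell density inside the source-adjacent region (bead
disk excluded from the area) divided by the density in the rest of the
box, evaluated on the final snapshot. The published evidence is a
density heatmap, not a scalar; this ratio is this package's
operationalization, and the region/annulus radii are configurable.
Single-seed indices fluctuate by ±0.2 around 1 for the null mode
(Poisson noise of ~56 in-region cells), so mode comparisons use 5-seed
means plus a seed-wise ordering check.

**Two branches** (`scenario_two_branches`): two vertical capsule loops
(straight-run length 8, width 2.4, 64 vertices) flanking the source at
±3.5 from the center; the **bead–branch distance** is the minimum over
all chain segments of the distance to the bead surface, floored at
contact, recorded at every snapshot. With migration off the inflating
branches approach the bead monotonically (post-transient jitter below
0.1 per snapshot interval); with migration on the condensation holds
the final distance several-fold higher at the matched seed and horizon.

## Metrics layer

The metrics operate on plain point sets and polylines, so they apply to
segmented micrographs as well as simulation output; coordinates carry a
declared unit string (dimensionless for the simulator, μm for
micrograph data). Nearest-point computations use full segments via
`shapely`; projection ties resolve to the smaller arclength. Density
fields are mass-normalized Gaussian kernel sums (they integrate to the
number of points, matching count-based densities). ROI membership is
half-open so tiled ROIs partition points exactly. The mark CDF along a
branch is normalized arclength from the declared tip, which must be an
endpoint of the polyline.

## Synthetic fixtures

The generators emulate the statistical structure the metrics assume:
uniform clouds (null condition), a Gaussian-enriched cluster around a
known center (condensation, analytically tractable enrichment), and
parallel branch pairs with marks placed uniformly or by a truncated
exponential from the tip (decay scale 0.15 of branch length, loosely
mimicking steep-then-plateau proliferation profiles). They provide
ground truth for detection-accuracy tests. They do not emulate
segmentation noise, anisotropic condensation shapes, curved branches,
or label misclassification — so passing recovery tests bounds metric
correctness on clean geometry only, not robustness to imaging
artifacts.

## Known limitations

* 2D only; no adhesion or attraction forces, no morphogen diffusion
  field (the source acts through a sharp-edged region), no cell death,
  no chain remodeling (fixed vertex count).
* Explicit Euler with fixed dt; stiff parameter choices (large k's with
  large dt) can destabilize the integration, which is detected and
  reported, not corrected.
* The condensation index depends on the region radius R and measures
  enrichment, not compaction; a dense ring hugging the bead and a
  diffuse cloud filling the region score alike.
* Proliferation uses a floor rule, so small regions with p·N < 1 add no
  cells at all rather than adding them stochastically.
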