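# Methods

This note records the models, conventions, numerical choices and known
limitations of the toolkit, in the order the pipeline runs.

## Beam models

**Depth-dose curves.** Each nominal energy (2, 3, 4, 5, 6, 10 MV) is
represented by a percent-depth-dose curve anchored to published Monte Carlo
water-phantom data for a 10 × 10 cm field at 100 cm SSD: six
depth-at-percent anchors (100% at dmax down to 50%) and four
percent-at-depth anchors (surface, 10, 20, 30 cm). The curve is a monotone
shape-preserving PCHIP interpolant through the merged anchors, which
guarantees anchor fidelity (every anchor is reproduced exactly) and
monotonicity on both sides of dmax without inventing physical parameters
(no attenuation coefficient or build-up model is fitted). Beyond the 30 cm
anchor the curve decays as a single exponential with rate fitted to the
last two anchors; this matters only for exit-dose look-ups of very deep
scenarios. Where both simulated and measured anchors exist, the simulated
values drive the model (the selector emulates a simulation-based workflow);
measured values are carried as metadata only, and the choice is exposed by
loading a user anchor file.

**Beam quality.** TPR₂₀,₁₀ is computed as %D(20)/%D(10) directly from the
curve. Because the anchors are interpolated exactly, the six published
values (0.446, 0.496, 0.528, 0.555, 0.579, 0.627) are reproduced to three
decimals, and the index is strictly increasing with nominal energy.

**Lateral profiles.** Off-axis ratio is an ideal rectangular field
convolved with a Gaussian penumbra: 0.5·[erf((w−x)/σ√2) + erf((w+x)/σ√2)]
for half-width w. Defaults σ = 0.3 cm (≤6 MV) and 0.4 cm (10 MV) reflect
the broader penumbra of higher energies. The horn-shaped unevenness of
large open fields is deliberately not modeled: beamlet weighting during
inverse planning absorbs fluence non-flatness, so a flat core is the
appropriate abstraction.

## Phantoms and geometry

Coordinates are right-handed patient coordinates in cm (x lateral, y
anterior-posterior, z longitudinal); a voxel occupies a half-open box;
gantry angle 0 enters anteriorly and increases clockwise viewed from the
feet; SAD is 100 cm. Density is assigned by region label (water 1.0, lung
0.25, bone 1.4, air 0.001) — CT-number calibration is out of scope.

The selector calibration phantom is a uniform water slab with a spherical
target of diameter TS centered at depth EP on the central axis; its
generator enforces EP ≥ TS/2 and a slab thick enough to contain the target.

The three archetypes emulate broad anatomical situations, not specific
patients: `lung_like` (thorax ellipse, two 0.25-density lungs, solid tumor
inside one lung, spinal cord and esophagus), `deep_pelvic` (large ellipse,
central target ≥ 9 cm deep, two bony femoral structures, rectum),
`brain_like` (small ellipse with a bone shell, target abutting brainstem
and chiasm). The seed jitters the target position within ±0.5 cm through a
dedicated generator, so each (name, seed) pair is bit-reproducible. What
these phantoms do *not* emulate: real CT heterogeneity textures, organ
shapes, or the published per-beam path lengths of actual patients — tests
passing on archetypes demonstrate the machinery, not clinical dosimetry.

Default spacing is 2.5 mm; geometry unit tests refine to 1–2 mm, and
planning tests coarsen to 5 mm to keep problem sizes at a few tens of
thousands of voxels (the slab planning phantom used throughout the tests is
24 × 32 × 24 ≈ 18k voxels with ~180 beamlets over five beams).

## Ray tracing

Radiological path length is the exact line integral of relative density
over the parametric voxel walk (Siddon-style: plane-crossing parameters per
axis, merged and clipped), additive over subsegments to 1e-6 cm. The four
special points are the first/last BODY and PTV crossings; EP integrates
density from skin to the isocenter (even when the isocenter is not the
target center); TS integrates density over in-target subsegments only, so
a ray crossing a disconnected target uses first entry and last exit. A ray
missing the target raises a distinct error so callers can drop the angle.

## Energy selector

The four-point doses for a candidate energy are read off its PDD curve at
depths 0, EP−TS/2, EP+TS/2 and an exit depth. Conventions left open by the
emulated workflow are explicit in `SelectorConventions`:

- **Score form** (default `cosine`): Σωᵢ·Dᵢ·dᵢ / √(ΣDᵢ²·Σdᵢ²). The
  similarity as literally typeset in the source material lacks the square
  root (`no_sqrt`), which destroys scale invariance; the cosine form is the
  default because the score is called a correlation coefficient and
  scale-freedom is clearly intended. A mean-centred `pearson` variant is
  also available.
- **Exit depth** (default 2·EP): a symmetric isocentric water slab. The
  emulated table's exact convention is unstated.
- **Weights** ω = (0.5, 1, 1, 1) applied in the numerator only, as printed.

Deep targets (EP > 18 cm) take 10 MV as a hard override before scoring;
exact score ties break to the lower energy (the modality's low-energy
preference); table look-up rounds EP/TS to the nearest node with half-way
ties toward the smaller value.

**Reproduction of the published look-up table is convention-limited.**
Under the defaults the generated table agrees with the published one on
49.4% of the 243 printed cells (42.8% under the literal no-sqrt form;
a Pearson-centred score with exit depth EP+TS reaches 68.3%). The cosine
score orders energies almost monotonically for most EP/TS — its margins,
reported per cell by `compare_to_reference`, are large, so the disagreement
is not a rounding effect: the published table's structure is not
recoverable from the ten printed anchors per energy plus the printed score
definition alone. The comparison report (generated vs published energy and
score margin per cell) is therefore part of the module's contract, and
agreement percentages are documented rather than asserted. 2 MV appears
nowhere over the published table's populated domain (it wins only two
extreme-shallow cells that are blank in the published table), and every
EP ≥ 18 column is 10 MV.

## Dose engine

Each beam is divided into 1 × 1 cm beamlets at the isocenter plane,
covering the target's beam's-eye-view projection plus one margin ring. The
deposition coefficient is separable: PDD at the water-equivalent depth
along the beamlet axis (radiological path from skin, no lateral
heterogeneity correction — first-order pencil beam), off-axis ratio at the
lateral distance back-projected to isocenter scale, and the inverse-square
factor. Columns are normalized so the open-field composite equals 1.0 at
water-equivalent dmax on the central axis, and entries below 1e-4 of their
column maximum are dropped (recorded in metadata). The engine is
deterministic; it stands in for Monte Carlo beamlet scoring, and the
selector and optimizer are agnostic to the DDC provenance. Not modeled:
scatter, electron transport, interface build-up/build-down, collimator
leakage and transmission.

## Inverse planner

The objective is quadratic in dose: Σ_target (dᵢ − p₀)² plus r-scaled DV
penalties for the target (≤ 2 constraints; defaults: ≤2% of voxels below
0.98·p₀ and ≤2% above 1.08·p₀ — the bounds are conventions, the emulated
workflow never prints its values) and for each organ at risk. A DV
constraint (structure, p, v%, direction) flags exactly those voxels that
violate it *beyond* the allowed volume fraction: for an upper constraint
the hottest v% may exceed p unflagged, the remaining voxels above p are
flagged (the standard DVH-penalty completion of a per-point flag
definition); lower constraints mirror this on the coldest fraction.

Optimization is projected gradient descent: flags are frozen each
iteration, making the objective exactly quadratic, so the line search uses
the closed-form minimizer along the negative gradient (one sparse matvec)
followed by projection onto x ≥ 0 with Armijo backtracking. Every 5
iterations a subspace polish minimizes the frozen-flag least-squares system
over the free variables (x > 0 or gradient pointing inward) via LSMR, with
the projected step backtracked to preserve monotone descent
(Moré–Toraldo-style gradient projection). Plain fixed-step steepest descent
was evaluated first and stalls one to two orders of magnitude above the
constrained least-squares optimum on realistic beamlet matrices (nearly
collinear penumbra columns); with the polish the optimizer reaches a
nonnegative-least-squares oracle to ~1e-10 relative on the no-constraint
problem. The penalty factor starts at r = 1 and doubles every 20
iterations; convergence is declared when the relative objective change
stays below 1e-5 for 5 consecutive iterations, with a 500-iteration cap
and an optional wall-clock limit. All dose points of every scored
structure are used (no sampling), and the algorithm is deterministic.

Initialization sets weight 1 for beamlets whose axis crosses the target
and 0 elsewhere (the beam's-eye-view aperture standing in for a
planning-system field outline).

## Plan evaluation

Dq% is the inverse empirical CDF with linear interpolation between sorted
voxel doses (the convention is not uniquely fixed by the emulated
workflow; this one makes D95%-normalization exact). Plans are normalized
by scaling so PTV D95% equals the prescription. DVHs are stored as exact
sorted doses; binning (0.05 Gy) is for plotting only. Integral dose over
BODY∖PTV is reported both as mean dose (Gy) and as dose-volume product
(Gy·L) because both conventions appear in practice. Report rounding: doses
1 decimal, HI 2 decimals, relative differences 1 decimal.

## Pipeline

A run config (YAML) fixes the phantom source, beams (energy fixed or
`auto`), prescription, constraints and optimizer controls. The pipeline is
deterministic given the config: rerunning produces bit-identical weights,
dose and metrics. Artifacts are CSV/JSON plus HDF5 for grids; the manifest
records the config hash, package version, problem sizes and per-beam
energy rationale (EP, TS, chosen MV, score margin).

## Known limitations

- The pencil beam ignores lateral heterogeneity along off-axis paths and
  all scatter; dose in low-density regions is only first-order correct.
- The published EP × TS table is reproduced in structure (deep override,
  no 2 MV, monotone trends) but not cell-for-cell; see above.
- Unconstrained plans can show large hot spots outside the target —
  physically meaningful OAR constraints are the user's responsibility.
- DVH-penalty objectives are nonconvex; the optimizer finds a good local
  minimum from the aperture start, not a certified global one.
- Archetype phantoms are schematic; no claim is made that planning metrics
  on them reproduce patient-level published values.
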