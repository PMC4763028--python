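# emxplan

A desk-scale toolkit for **energy-modulated photon radiotherapy (EMXRT)**
planning: instead of planning every gantry angle with one fixed accelerating
potential (the usual 6 or 10 MV), the beam energy at each angle is chosen
from a pool of 2, 3, 4, 5, 6 and 10 MV according to the patient anatomy seen
by that beam, and the beamlet intensities of the resulting mixed-energy beam
set are optimized together. The toolkit is aimed at medical-physics research
and teaching: it runs entirely on synthetic voxel phantoms and printed
water-phantom beam data, with no patient data, DICOM, or Monte Carlo engine
required.

## What it implements

**Beam models.** Percent-depth-dose (PDD) curves for the six-energy pool are
monotone shape-preserving (PCHIP) interpolants anchored to published Monte
Carlo water-phantom data (10 × 10 cm field, 100 cm SSD), with a
single-exponential tail beyond the deepest anchor. Beam quality is the usual
index TPR₂₀,₁₀ ≈ %D(20)/%D(10); the fitted curves reproduce the published
values (0.446 at 2 MV up to 0.627 at 10 MV) to three decimals. Lateral
profiles are flat-core/error-function-penumbra models.

**Energy selector.** For a beam crossing the patient, four special points
are traced: skin entrance (1), target entrance (2), target exit (3) and
beam exit (4). With the water-equivalent effective path length EP
(skin → isocenter) and tumor size TS (water-equivalent in-target length),
each candidate energy is scored against the ideal dose pattern
D_ideal = (10, 100, 100, 10)% by a weighted cosine similarity

    CC(E) = Σᵢ ωᵢ · D_ideal(i) · d_PDD(i; E) / √(Σᵢ D_ideal(i)² · Σᵢ d_PDD(i; E)²),

with weights ω = (0.5, 1, 1, 1) (skin down-weighted) and d_PDD read off the
energy's PDD curve. The maximum-CC energy wins; targets deeper than
EP > 18 cm take 10 MV outright, and EP must exceed the target radius.
A pre-computed EP × TS look-up table (EP 2–21 cm, TS 2–16 cm) makes the
selection a table look-up per beam.

**Ray tracing.** Exact Siddon-style voxel walks give radiological path
lengths and the four special points on any voxel phantom.

**Dose engine.** A deterministic divergent pencil-beam kernel scores the
dose deposition coefficient (DDC) aᵢⱼ of each 1 × 1 cm beamlet j to each
voxel i as PDD(water-equivalent depth) × off-axis ratio × inverse-square,
stored sparsely; dose is the superposition dᵢ = Σⱼ aᵢⱼ xⱼ.

**Inverse planner.** Beamlet weights x ≥ 0 minimize a quadratic objective:
target term Σ(dᵢ − p₀)² plus dose-volume (DV) penalty terms for target and
organs at risk, gated by per-voxel violation flags with DVH volume
bookkeeping and scaled by a penalty factor r that escalates during the run.
Optimization is monotone projected gradient descent with exact line search
and periodic subspace minimization; initialization is the target's
beam's-eye-view aperture (weight 1 inside, 0 outside).

**Plan evaluation.** Plans are normalized so D95% of the target equals the
prescription; metrics include Dmean, D2%, D50%, D95%, D98%, the homogeneity
index HI = (D2% − D98%)/D50%, VxGy, and normal-tissue integral dose. Paired
plans are compared via relative difference 100% × (b − a)/a.

**Synthetic phantoms.** A water-slab/spherical-target calibration phantom
and three deterministic patient-like archetypes (`lung_like`,
`deep_pelvic`, `brain_like`) with named structure masks.

## Worked example

Score the energy pool for a beam with EP = 9.9 cm and TS = 5.4 cm:

```
$ emxplan select --ep 9.9 --ts 5.4
selected: 10 MV
   2 MV  CC = 0.7437
   3 MV  CC = 0.8089
   4 MV  CC = 0.8511
   5 MV  CC = 0.8844
   6 MV  CC = 0.9000
  10 MV  CC = 0.9210
```

Each line is the four-point similarity of that energy's depth-dose pattern
to the ideal (low skin/exit dose, full target dose); the highest-scoring
energy is selected. Inspect a beam model:

```
$ emxplan beams show --energy 6
6 MV  dmax = 1.5 cm
...
TPR20,10 = 0.579
```

A full planning run takes a YAML config (phantom archetype, beams with
energy `auto` or fixed, prescription, DV constraints):

```yaml
# plan.yaml
archetype: lung_like
seed: 1
spacing_cm: 0.5
prescription_Gy: 50.0
max_iterations: 100
beams:
  - {gantry_deg: 0, energy: auto}
  - {gantry_deg: 120, energy: auto}
  - {gantry_deg: 240, energy: auto}
```

```bash
emxplan run --config plan.yaml --out run_out/
emxplan compare --a run_fixed6/metrics.csv --b run_out/metrics.csv
```

`run_out/` contains per-structure metrics, DVH curves, beamlet weights,
per-beam energy assignments (EP, TS, chosen MV, score margin) and a
provenance manifest; `compare` adds the relative-difference column between
a fixed-energy baseline and the energy-modulated plan.

## Scope and limits

The dose engine is a first-order pencil-beam model, not Monte Carlo: no
scatter modeling, electron transport, or interface build-up/build-down
effects. Published patient-level dose tables depend on real CT anatomy and
a Monte Carlo engine and are out of scope; see `docs/methods.md` for the
model assumptions, conventions and known limitations.
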