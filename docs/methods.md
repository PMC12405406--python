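# Methods

This note documents the models, conventions and numerical choices behind
`beamqa`, in the spirit of a package's statistical/methods appendix. It
describes what the code computes and why the defaults are what they are; it
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The analytic beam model

`dose_model` is a synthetic-data generator, not a transport code. Its job is
to produce dose data with the *structure* of megavoltage water-phantom
measurements — a build-up region, quasi-exponential fall-off, flat-cored
profiles with error-function penumbrae, field-size-dependent output, and
Monte-Carlo-like noise — so that every analysis routine can be exercised and
its failure modes probed without access to measured or simulated data sets.

### Central-axis depth dose

    D(z) ∝ (1 − exp(−k·z)) · exp(−μ·z)

The first factor models electronic build-up (secondary-electron equilibrium
established over the first centimetres), the second primary-photon
attenuation. The form was chosen because its maximum has a closed form,

    z* = (1/k) · ln(1 + k/μ),

which the tests use as an independent oracle for `find_dmax`.

Defaults are solved, not tabulated. For each energy label, μ and k are the
joint numerical solution (nested Brent root finds, tolerance 1e-13) of:

* z* equals the clinical build-up depth — 1.4 cm (6 MV), 2.5 cm (12 MV);
* the beam-quality ratio D20/D5 equals the measured 10×10 cm² value —
  0.417 (6 MV), 0.498 (12 MV).

This yields μ ≈ 0.0583 /cm (6 MV) and ≈ 0.0465 /cm (12 MV). These are
*effective* attenuation coefficients: because the model omits the
inverse-square divergence term, μ absorbs it, and comes out somewhat larger
than narrow-beam water values. A two-parameter shape pinned to d_max and
D20/D5 does not also reproduce the absolute PDD values at 5/10/20 cm that a
real beam shows (e.g. it gives PDD(10 cm) ≈ 62% where a clinical 6 MV beam
reads ≈ 72%); analyses that need those exact values take the printed numbers
as *inputs* (see the report tests) rather than regenerate them.

The multiplier `1 + scatter_slope·(field_size − 10)` scales the raw
curve but is constant in depth, so it cancels when the curve is normalized
to its maximum; the field-size dependence of *absolute* output is therefore
carried by a separate output-factor curve (below), and normalized PDD
curves are field-size independent in this model. This is a deliberate
simplification: the percent-level PDD-versus-field-size trend of real beams
is not emulated.

### Lateral profiles

    D(x) ∝ [Φ((w/2 − x)/σ) + Φ((w/2 + x)/σ) − 1] · (1 + h·(2x/w)²) · T(x)

with Φ the standard normal CDF, σ = `penumbra_sigma` (mm), w the square
field width projected to depth, w = 10·field_size·(SSD + d)/SSD (mm), and
h = `horn_amplitude` the off-axis over-dose ("horns") that flattening-filter
beams show. The symmetric two-CDF form is used (rather than the equivalent
difference of CDFs) because it is *exactly* even in floating point, which
the evenness invariant tests rely on. Profiles are normalized to 100 on the
beam axis (the off-axis-ratio convention).

For a single edge, the 80%–20% distance is 2·√2·erfinv(0.6)·σ ≈ 1.683·σ;
this closed form is the oracle for `penumbra_widths`. Defaults σ = 3.1 mm
(6 MV) and 4.5 mm (12 MV) put the default penumbrae in the 5–8 mm range
typical of the two energies at 10 cm depth; h = 0.09 puts default flatness
near 106%, typical of flattened beams.

The wedge is physical: zero thickness at the −x field edge, linearly
thickening across the field, giving transmission T(x) = exp(−g·(x + w/2)/10)
with g = `wedge_transmission_gradient` (per cm). After axis normalization
this is exactly the tilt exp(−g·x/10); the *raw* central-axis dose carries
the factor exp(−g·w/20), which is what makes the generated wedge factor
less than 1 and decreasing in g. Because the model has no scatter, the
generated wedge factor *decreases* with field size, opposite to the
scatter-driven increase real wedged beams show; wedge-factor trend analyses
should therefore use measured tables as inputs.

### 3-D grids, perturbations, noise

Grids are separable products pdd(z) × profile(x; z) × profile(y; z),
normalized so the noiseless global maximum is exactly 100 (the division is
ordered `100·(raw/peak)` so the maximum is bit-exactly 100). Separability
makes the central axis of a hornless grid equal the 1-D curve to machine
precision — a cheap strong self-test — and is explicitly not a claim about
real 3-D dose.

`perturb_grid` resamples at shifted coordinates (linear interpolation, edge
values held), rescales, and applies noise; it is the controlled way to
manufacture gamma test pairs with known disagreement.

Noise is multiplicative Gaussian, dose·(1 + ε), ε ~ N(0, noise_sd²),
clipped at zero, generated by `numpy.random.default_rng(seed)`. This mimics
Monte-Carlo statistical uncertainty scaling with local dose. Fixed seed ⇒
bit-identical outputs; every generator call derives its randomness from the
params' own seed field.

### Output factors

Absolute output versus field size uses a saturating scatter curve
S(f) = A − B·exp(−c·f), solved exactly through three anchors:
(1 cm, 0.55), (10 cm, 1.0), (40 cm, 1.22) for the phantom output factor
S_cp — the published clinical range for these beams — and the much gentler
(0.94, 1.0, 1.03) for the head scatter factor S_c, for which only the
increasing trend is documented. The curve is monotone by construction and
equals 1 exactly at the 10×10 reference. `central_axis_dose` deliberately
excludes the `scatter_slope` term so the factor sweep honours the anchors
exactly.

## Metric conventions

* **Field width** is defined by the 50%-of-central-axis-dose crossings; the
  "central 80% of the field width" region is centred on the midpoint of
  those crossings. All crossings use linear interpolation between adjacent
  samples, scanning outward from the axis, so ties resolve toward the axis.
* **Flatness** is D_max/D_min × 100 over the central region (values ≥ 100,
  matching how commissioning tables print it). The alternative
  "difference over sum" definition found in some texts would give values
  near 0–5%; this package implements the ratio form.
* **Symmetry** is the worst mirrored point-pair ratio D(x)/D(−x), oriented
  ≥ 100, over the central region, with the mirror dose interpolated. A
  single worst-pair number matches how QA tables report symmetry slightly
  above 100%.
* **Penumbra** is the 80%–20% lateral distance per side, levels taken as
  percentages of the central-axis dose, sides reported separately plus
  their average.
* **find_dmax** returns the maximum sample's depth (ties toward the surface);
  at a strict interior maximum it refines by a 3-point parabola and snaps
  back to the grid spacing, so results are reported at the scan's own
  resolution. On plateaus and boundary maxima no refinement is attempted.
* **normalize_pdd** divides by the maximum sample (the dose at the sampled
  z_max), so PDD(z_max) = 100 exactly and the operation is idempotent.
* **Rounding in reports**: ratios 3 decimals, percentages 1–2 decimals,
  penumbra 2 decimals — the precision of the clinical tables these reports
  mirror.

## The gamma engine

γ(r) = min over evaluated positions e of
√[(|e−r|/r_m)² + ((D_e − D_r)/D_m)²].

* **Semantics**: the evaluated distribution is linearly interpolated on a
  lattice of spatial offsets of pitch `interp_step_mm` (default r_m/10) out
  to `search_limit_factor`·r_m (default 3·r_m) around each reference point;
  γ is the exact minimum over that candidate lattice. Candidates falling
  outside the evaluated domain are skipped, so edge points are evaluated
  against the covered portion.
* **Normalization** defaults to "global" (D_m as a percentage of the global
  reference maximum), the standard clinical 3%/3mm practice; "local" uses
  the reference dose at each point and refuses zero-dose points. The
  low-dose threshold defaults to 0 (no masking). Both are configuration,
  not baked-in assumptions.
* **Direction** is fixed reference → evaluated (γ is not symmetric); report
  headers record it.
* **Algorithm**: offsets are visited nearest-first with an early exit once
  the spatial term alone exceeds the current worst running minimum; this
  changes nothing about the result, only the cost. `gamma_oracle`
  recomputes the identical quantity by plain exhaustive enumeration per
  reference point — no sorting, no early exit, no shared state — and exists
  so tests can cross-check the optimized path against an algorithmically
  independent one. Both routes minimize over the same well-defined discrete
  lattice, which is why tests can demand agreement to 1e-6 (observed:
  bit-identical). A separate property test checks that refining the lattice
  step never increases γ, bounding the discretization error empirically.
* **Degenerate inputs**: empty distributions, dimensionality mismatches and
  all-masked maps raise typed errors rather than returning silent NaNs.

Because the discretization is a lattice of pitch r_m/10, a γ value carries a
resolution floor of order (step/r_m)² = 0.01 in γ²; tighten
`interp_step_mm` when values very close to 1.0 must be adjudicated.

## File formats

The dose-grid dialect is a self-describing text format: `#axis name unit n
values…` headers followed by one dose per line in row-major x,y,z order,
serialized with 17 significant digits so IEEE doubles round-trip exactly.
Scans are two-column CSV with `#key value` metadata comments. Readers
validate axis monotonicity, value counts and non-negativity and name the
offending line. DICOM RT Dose import applies the dose-grid scaling factor,
rebuilds the depth axis from the frame offset vector (uniform offsets only)
and marks the unit Gy; there is no DICOM export, since the toolkit consumes
dose data rather than producing clinical objects.

## What the synthetic data does and does not show

Passing tests on generated data demonstrate that the *analysis* code is
correct against closed forms and exhaustive oracles, that the pipeline is
deterministic under seeding, and that the metrics behave with the right
monotonicities and invariances. They do not validate the beam model against
any physical machine: the generator has no inverse-square term, no scatter
kernel, no spectral hardening, no detector volume averaging, and separable
3-D dose. Quantities that depend on undeposited machine data (absolute
gamma pass rates of a specific accelerator, measured flatness/penumbra
tables, wedge-factor field-size trends) are treated as printed inputs where
analyses need them, never as model outputs.

## Problem sizes

The default analyses are desk-scale by design: depth-dose curves of ~300
points, profiles of a few hundred points, grids well under the 2×10⁶-node
limit, and oracle cross-checks on 1-D scans of ~35 points and 2-D grids of
8×8 reference points — sizes at which the exhaustive oracle is exact and
fast and the whole suite runs in seconds.
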