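# Methods

This note documents the models and numerical choices behind `texqa`: how a
plan becomes a fluence map, how the map becomes a texture panel, how
delivery accuracy is measured, what the synthetic generators emulate, and
where the genuinely open design decisions were resolved.

## Plan model

A plan is a list of beams; a beam is an ordered control-point sequence with
per-pair MLC bank positions (mm at isocenter, IEC 61217 beam-limiting-device
coordinates, bank A the negative-direction bank as in DICOM MLCX encoding),
gantry angle, and cumulative meterset weight in [0, 1] (nondecreasing,
0 at the first control point, 1 at the last). DICOM-RT Plan files are read
with pydicom; control points that omit MLC positions, gantry angle or jaws
inherit the previous control point's values, per DICOM semantics, and the
first control point must carry them. Cumulative weights are rescaled by the
final cumulative meterset weight when that is not 1. Jaws default to
±200 mm (a no-op clip) when absent. A versioned JSON format mirrors the
same structure so fixtures and machine-log records need no DICOM; vendor
binary trajectory logs are out of scope — logs enter as plan-shaped JSON
snapshots (clinical log systems can export DICOM-RT-shaped records), and a
resampling helper aligns denser logs to plan control points linearly in
cumulative MU.

## Fluence integration

Pixel value = Σ over control points of (MU share × open-area fraction of
the pixel). Choices that matter:

* **MU share per control point.** A plan stores cumulative weights at
  control points, but an aperture is a snapshot, not an interval. The
  default trapezoidal share, ΔMU(cp_k) = total_MU × (w_{k+1} − w_{k−1})/2
  with duplicated end weights, splits each interval's MU evenly between its
  two bounding apertures; it is symmetric under sequence reversal and sums
  exactly to the beam MU. A `left` mode assigns each interval to its
  starting aperture instead.
* **Partial pixels.** Each leaf-pair row opens a rectangle, so coverage is
  computed exactly as the product of x- and y-overlap fractions, removing
  1 mm aliasing at leaf tips. A center-in test is available for speed.
* **Grid.** Default 1 mm spacing, extent = union of jaw-clipped apertures
  over all control points padded by 5 mm, with pixel centers on the
  half-millimetre lattice so equal plans give equal grids. Before texture
  analysis the map is cropped to the bounding box of nonzero fluence
  (margin configurable, default 0): background zeros dilute every
  co-occurrence feature, so map extent must be explicit, not an accident
  of the jaw setting.
* **Idealization.** No leaf transmission, tongue-and-groove, rounded leaf
  tips or scatter: fluence is purely MU-weighted geometric open time. This
  is the right object for a plan-complexity metric (it depends only on
  plan content), but it is not a deliverable-dose model.
* **Quantization.** level = round_half_up(127 × value / max). Half-up
  rounding is used rather than banker's rounding so results are
  reproducible across platforms and languages; the maximum of every nonzero
  map is exactly 127, making the panel invariant to MU rescaling.
* All beams of a plan are pooled into one map; multi-arc plans therefore
  yield one texture panel per plan, not per arc.

## Texture features

Co-occurrence matrices are 128 × 128, symmetric (each pair counted in both
orders, so four angles cover all eight neighbor directions and the marginal
distributions coincide), normalized before feature extraction. The offset
convention, in (col, row) with row increasing downward, is (d, 0), (d, −d),
(0, −d), (−d, −d) for 0°, 45°, 90°, 135°: a diagonal step moves d pixels in
each axis, i.e. d·√2 mm on the 1 mm grid. Note this differs from
scikit-image's `graycomatrix`, which rounds sin/cos offsets (its d = 10
diagonal is ~7 pixels per axis) and labels the up-right diagonal 135°; the
test suite carries the exact mapping.

Feature conventions that the literature leaves open:

* **Logarithm base.** Entropy uses log₁₀ by default (configurable to e or
  2). With 128 levels the base-10 entropy of a fluence map lies in roughly
  0–4.2; natural log would scale all entropies by ln 10/1 ≈ 2.3.
* **Variance.** The marginal form Σᵢ (i − μ)² pₓ(i) with μ the marginal
  mean (Haralick's sum-of-squares variance); a joint-mean form is available
  behind a flag, and the two coincide for symmetric matrices in practice.
* **Degenerate correlation.** A matrix concentrated on one gray level has
  zero marginal variance and an undefined correlation; it is returned as
  NaN, and direction averaging uses the defined directions only, recording
  how many were defined. Nothing is silently zeroed.

The panel is the 6 features × d ∈ {1, 5, 10} = 18 values per plan.
Small d probes adjacent-pixel structure (leaf-width-scale modulation);
d = 10 probes 10 mm structure where modulated and smooth plans separate
most cleanly in this package's synthetic cohorts.

## Gamma analysis

Global 2D gamma on absolute-dose planes:
γ(r) = min over reference positions r′ within the search cap of
√(|r′ − r|²/Δ² + (D_ref(r′) − D_meas(r))²/(δ·D_max)²), with Δ the
distance-to-agreement (mm), δ the dose criterion as a fraction of the
**reference plane's global maximum** (the natural reading of "global"
normalization; the normalization plane is configurable only in the sense
that the arguments can be swapped), and a 10% low-dose cutoff applied to
the measured dose against that same maximum. Numerics: the reference is
bilinearly interpolated; candidate offsets lie on a lattice of step Δ/10
out to a cap of 3Δ; offsets are visited in rings of increasing radius and
a point stops searching as soon as no farther ring can lower its γ, which
makes the exhaustive search cheap on mostly-agreeing planes. Points whose
minimum could lie beyond the cap are counted in `n_capped`. The
implementation is validated against a no-termination exhaustive search to
1e-3 on 50 × 50 planes; passing rates are monotone under loosening of
either criterion, and invariant to common rescaling of both planes.

## Mechanical errors

Mean absolute plan-vs-log differences at matched control points: per-leaf
MLC positions over both banks, gantry angles on the circle (wrapping at
360°), cumulative MU (planned cumulative MU = weight × beam MU). All leaf
pairs are included by default — the averaging set is part of the metric's
definition, so a `moving_leaves_only` option restricts to pairs whose
planned position changes, for sensitivity analyses. Summaries from repeated
QA sessions are combined by a component-wise mean.

## Spearman correlation

Midranks for ties; r is the Pearson correlation of rank vectors. For
n ≤ 9 the two-sided p-value is exact, by enumerating all n! permutations
of one rank vector; beyond that the t-approximation
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom. Constant input is an
error, not r = 0. Panel significance is raw p < 0.05 — deliberately
uncorrected, since the per-feature significant-correlation count is itself
the quantity of interest; a Benjamini–Hochberg option exists but is off by
default.

## Synthetic generators

* **Plans.** Leaf tips trace an ellipse (default semi-axes 30 × 40 mm,
  a mid-size target) intersected with each leaf-pair row, plus a Gaussian
  perturbation smoothed along the control-point and leaf axes by a moving
  average (window 5) and rescaled to amplitude σ_m — the modulation knob.
  Smoothing keeps trajectories low-frequency, as deliverable MLC
  trajectories are; crossed leaves collapse to their midpoint, and rows the
  ellipse never opens stay closed. Defaults: 72 control points (5°
  spacing over one arc), 20 uniform 5 mm leaf pairs, 400 MU — compact
  enough that a 40-plan study runs in well under a minute while the
  fluence maps (~70 × 90 px) still show rich texture. Meterset is uniform
  across control points by default; a sinusoidal option exercises the
  MU-weighting code path. Catalog geometries (60-pair HD and Millennium
  MLCs, with 2.5/5 mm and 5/10 mm leaf widths) are provided for realism
  when wanted.
* **Logs.** Recorded = planned + independent Gaussian noise per quantity;
  cumulative MU is kept nondecreasing by a running maximum (negligible at
  the default noise scales). Optional speed coupling adds noise
  proportional to per-control-point leaf travel.
* **Dose planes.** Reference = Gaussian-blurred (σ = 3 mm, a detector-like
  smoothing) fluence rescaled at 1 MU-pixel ≡ 1 cGy (arbitrary but fixed;
  global gamma is scale-invariant); measured = reference shifted along x
  plus multiplicative Gaussian noise. For the study the planes are
  block-averaged to 2 mm — coarser than the fluence grid, comparable to
  planar-array detector spacing — which keeps 40 plans × 4 criteria fast
  without changing any ordering the study relies on.
* **Study coupling.** In `coupled` mode the log noise scales and the
  dose-plane degradation grow linearly with σ_m, emulating the clinical
  situation in which heavily modulated plans are delivered less
  accurately; `independent` mode severs that link and serves as the null.

**What passing synthetic tests shows — and does not.** The synthetic cohort
establishes that the pipeline is correct and that the features respond to
modulation in the constructed direction (ASM falls, entropy rises, and both
correlate with delivery error when error is coupled to modulation). It does
not establish clinical effect sizes: real plans differ by treatment site,
not by a single amplitude knob; real MLC errors arise from servo dynamics,
not i.i.d. noise; and real measured doses include detector response and
setup error. Absolute feature values here are far from clinical ones
(synthetic maps are smaller and smoother), which is why the tests assert
signs, orderings and closed forms rather than magnitudes.

## Statistical check of the null study

Texture features of one plan are strongly inter-correlated, so the
"≈5% of cells significant under the null" check cannot use a plain
binomial band across all feature × measure cells. The test instead treats
each independent noise measure as one trial: with M measures, the mean
significant fraction has standard error at most √(0.05·0.95/M) even if all
18 features were perfectly correlated, and the test uses the corresponding
conservative 99% band with M = 600.

## Known limitations

* Planar gamma only; cylindrical-detector geometries are not modeled.
* Fluence is idealized (no transmission/tongue-and-groove), so features
  are plan-complexity metrics, not dose predictions.
* The DICOM reader targets MLCX-type beams; couch/collimator rotation and
  wedges are ignored, and non-MLC beams are skipped.
* Exact Spearman p-values are limited to n ≤ 9 by n! enumeration.
* Fluence maps are exchanged as CSV matrices with a JSON grid sidecar;
  image formats are intentionally not written by the core library to keep
  every artifact diffable text.
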