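# Methods

This note documents the models implemented in `fdmesh`, the choices made
where the design was genuinely open, and what the synthetic experiments
do and do not demonstrate.

## Unit-cell model

The braid surface is treated as a periodic tiling by rhombic pore cells
of side `S` (strut length, constant per device), wire width `ω`, and half
angle `α` between strut and device axis.  Cell area is `S² sin 2α`; each
cell owns two struts (`2Sω`) minus one wire-crossing overlap, the
parallelogram where two `ω`-wide strips meet at included angle `2α`
(`ω²/sin 2α`).  Metal fraction and porosity follow in closed form.  The
closed form is validated in the test suite against an independent
rasterization oracle that pixel-counts the union of the two strip
families over one period on a 2000² midpoint grid (maximum observed
deviation below 2·10⁻³ over 200 random cells).

Two consequences of the closed form are worth making explicit:

* Metal coverage is minimal (porosity maximal) at `α = 45°`, where the
  cell area peaks.  Devices braided steeper than 45° therefore *gain*
  porosity when first crimped below nominal.
* The valid half-angle interval is `{α : S sin 2α ≥ ω}`.  At both
  endpoints the crossing overlap saturates the cell and metal fraction
  equals exactly 1 (mesh closed); beyond them wires would overlap their
  neighbours and the formula loses meaning.  The interval is found by
  bisection on the saturation condition `ω − S sin 2α` (the metal
  fraction minus one has a double root at the boundary, so it cannot be
  bracketed directly).

Porosity is defined as free/total surface; the complementary metal
coverage is exported alongside it in field tables.  All interfaces take
and return degrees; radians are internal.

## Angle–diameter calibration and foreshortening

With a fixed number of wire crossings per circumference and fixed strut
length, the circumferential cell span is proportional both to the local
diameter and to `sin α`, giving `α(d) = arcsin(sin α_nom · d/φ_nom)` —
parameter-free given the nominal state and exact at `d = φ_nom`.  The
longitudinal cell-row span is `2S cos α`, so the device lengthens as it
is under-expanded; the row count `M = round(L_nom / (2S cos α_nom))` is
fixed per device and conserved across deployments, acting as the
discrete surrogate for conservation of wire length.

## Deployment march

Rows are placed sequentially from the distal anchor (arc length
increases distal → proximal; devices are anchored distally).  Each row's
diameter is looked up at its center via a short fixed-point iteration
(three passes; row length depends on the center diameter which depends
on the row length), capped at the nominal diameter — a braid cannot
expand past nominal, so oversized segments sit at 100% expansion.  There
is no sub-row tapering; `n_theta` (default 16) equally spaced
circumferential samples are evaluated per row.

Curvature modulation: the local longitudinal strain at circumferential
position θ is `ε(θ) = −κ (d/2) cos(θ − θ_normal)` (compression on the
inner wall, where the curvature normal points), clamped to |ε| ≤ 0.5,
and tilts the half angle through `cos α(θ) = cos α_row (1 + ε(θ))`, with
the result clamped into the valid angle interval.  For rows with
`α_row > 45°` — the clinically relevant regime for these braids — this
closes the mesh (lowers porosity) on the inner wall of a bend; the
ordering reverses below 45°, a direct property of the closed form.
Curvature is estimated by second differences of the centerline
(`np.gradient` twice), with curvature below 10⁻⁸/mm treated as straight
and given a fixed, documented reference normal so runs are reproducible.

Region summaries are unweighted means and population SDs over all
circumferential samples of rows whose center lies in the half-open neck
interval; no cell-area weighting is applied.

## Morphology index (MAAI)

Correlation-matrix PCA (not covariance: the descriptors mix mm and mm³
scales) of the standardized descriptors; the first eigenvector defines
the index, sign-anchored to a non-negative loading on the
largest-variance descriptor so that larger aneurysms score higher and a
negative occlusion coefficient reads as "smaller aneurysms occlude more
often".  The default descriptor set is {width, depth, neck_max,
neck_min}; a five-variable set adding volume is available.  For an
equicorrelated set at Pearson ρ the first component carries
`(1 + (p−1)ρ)/p` of the variance — the analytic check used in the tests
(ρ = 0.92, p = 4 → 0.94).

## Outcome models

* **Occlusion Logit** — maximum-likelihood logistic regression (via
  statsmodels) of the binary occlusion outcome on porosity, mesh angle,
  expansion, MAAI and brand (dummy-coded against the alphabetically
  first observed level).  Perfect/quasi-perfect separation is detected
  and flagged on the fit, not raised; constant covariates are an error,
  never a silent NaN.
* **TTO ANCOVA** — OLS of TTO (months) on brand, an age term, and the
  continuous covariates in a caller-chosen entry order, restricted to
  occluded cases with TTO ≤ 12 months.  The decomposition is sequential
  (entry-order, type-I) sums of squares, mirroring the "correction
  order" reading of covariate adjustment: fitted values, residuals and
  R² are invariant to the order, only the per-term attribution changes,
  and the term SS plus residual SS always reproduce the total SS.
  Marginal (drop-one) F tests are reported for completeness.
* **Age handling** — age in years cannot enter as a one-level-per-year
  factor at cohort sizes of interest, and its effect is plausibly
  non-monotone (young and old patients showing similar TTO).  Default is
  categorical tertiles (boundaries at the 1/3 and 2/3 sample quantiles
  of the fitted subset); continuous-linear and continuous-quadratic
  options are available.
* **Diagnostics** — Shapiro–Wilk on the residuals and median-centered
  Levene (Brown–Forsythe) across a chosen factor's groups; groups with
  fewer than two residuals are excluded with a warning.  No
  multiple-testing correction is applied anywhere; fits carry that note
  in their metadata.

TTO is summarized as the arithmetic mean over occluded cases with its
standard error (sample SD/√n).  TTO is treated as the observed follow-up
time of occluded cases; censoring/survival modeling is out of scope.

## Synthetic truth and cohort generation

The generator emulates the study conditions of a retrospective,
four-brand, 64-aneurysm cohort.  Defaults anchor every value the
emulated study pins down: brand mix 8/8/26/22; follow-ups uniform on
6–12 months; mean expansion 87% (SD 7%); occlusion rate 51/64; MAAI
logit slope −0.25; TTO mean 6.92 months; TTO R² 0.92.  Where the study
conditions are not pinned down, values were fixed once at realistic
levels: ages uniform 30–75; vessel taper up to 10%; centerline curvature
up to 0.05/mm; aneurysm depth log-normal with median 3.28 mm and log-SD
0.70 (matching realistic quartile spreads), the other descriptors
similar.

Key calibrations, all deterministic given a cohort:

* **Morphology copula.**  Descriptors are log-normal with a Gaussian
  copula whose latent correlations are pairwise pre-compensated so the
  *raw-scale Pearson* equicorrelation equals the target ρ = 0.92 (naive
  log-space correlation would attenuate on the raw scale and shift the
  MAAI variance fraction).  neck_min/neck_max ordering is enforced by
  min/max of the pair.
* **Intercept centering.**  The logistic linear predictor is centered at
  the realized covariate means, so the intercept is the population
  occlusion log-odds (log(51/13)); the TTO systematic part is centered
  on the occluded subset at 6.92 months.  Effective raw-scale intercepts
  are emitted in the truth sidecar for recovery tests.
* **Residual scale.**  The TTO residual SD is set to
  `sd(systematic) · sqrt((1−R²)/R²)` per cohort, making the generating
  in-sample R² exactly 0.92 without touching the slopes.
* **Truncation.**  TTO draws are truncated to (0, 12] by residual
  redraws — at the default truth the truncation probability is ~10⁻⁷,
  so the linear model the fits assume is effectively exact.  The
  follow-up of an occluded case is then drawn uniformly between
  max(6, TTO) and 12: the angiogram that observed the occlusion cannot
  precede it.  The TTO slope on MAAI is deliberately small (0.10):
  MAAI is a long-tailed covariate, and a large slope would push
  extreme cases against the 12-month bound, where truncation would bias
  the tiny residual scale that R² = 0.92 implies.
* **Brand independence.**  TTO brand offsets are zero by design: brand
  effects on TTO flow only through the mesh covariates.

The phantom-validation emulation adds iid Gaussian noise (default SD
0.02, clipped to [0, 1]) to the simulated porosity field and scores the
fraction of points whose prediction error is below 10% of the measured
value ("good estimates"), for the spatially resolved prediction and for
the constant manufacturer-tag baseline (porosity at nominal expansion).
On any deployment with non-uniform diameter the resolved prediction
strictly dominates; the margin depends on how far the phantom
expansions sit from nominal, and with the default phantom conditions the
tag baseline is less disadvantaged than in physically measured settings.

**What the generator does not emulate:** real 3DRA imaging and
segmentation variability, non-circular lumens, apposition/malapposition
and flared or telescoped devices, anti-aggregation and other patient
physiology, and any dependence structure between morphology and vessel
geometry beyond the neck-width link.  Passing recovery tests therefore
demonstrates the statistical machinery is correct and calibrated under
the stated generative model — not that the same effect sizes hold in
clinical data.

## Numerical choices

* Degrees at all public interfaces; radians internally.  Arc length in
  mm, zero at the distal end.
* Bisection tolerances: 80 iterations on the angle-range boundary
  (~10⁻²³ degrees, i.e. machine precision).
* Fixed-point row placement: 3 iterations, warm-started from the
  previous row.
* Straight-segment normal: Gram–Schmidt of the fixed reference vector
  (0, 0, 1) against the tangent, falling back to (1, 0, 0) near
  parallelism.
* Resampling grid: `linspace(0, L, round(L/ds)+1)` — endpoints exact,
  idempotent at a fixed `ds`.
* Population SDs (ddof = 0) in mesh summaries; sample SDs (ddof = 1) in
  cohort-level statistics.
* Dummy coding: reference level is the alphabetically first observed
  level, recorded in every fit.
* Problem sizes: the recovery experiment uses 300 replicates of n = 500
  cohorts and the null calibrations 500 replicates, sizes at which
  binomial noise on a 95% coverage proportion is ~1.3 percentage points;
  analytic checks use n = 2000.

## Known limitations

* The strain-based curvature modulation is first-order and clamped at
  |ε| ≤ 0.5; sharply bent vessels (κ·r approaching 1) are outside its
  regime.
* The angle–diameter law assumes free axial sliding of crossings
  (no friction); measured devices show hysteresis the model ignores.
* Device presets are illustrative calibrations, not manufacturer data;
  absolute porosity levels per brand should not be read clinically.
* Logit Wald intervals are asymptotic; at small n with the near-collinear
  mesh covariates (porosity, angle and expansion are all driven by local
  expansion) individual coefficients are imprecise even when the fit is
  sound, and separation-flagged fits should be interpreted via the flag.
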