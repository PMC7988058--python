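# Methods

## Filtration-histogram texture analysis

### Model

Each axial CT slice is convolved (2D, in-plane only) with a
Laplacian-of-Gaussian (LoG) band-pass kernel. A zero-sum kernel removes the
local mean, so the filtered image measures intensity *structure* at a
chosen spatial scale rather than absolute attenuation. The scale is
parameterised by the spatial scale filter value SSF in mm — the approximate
diameter of the structures the filter highlights — with SSF 0 meaning no
filtration (raw HU). The conventional labels are fine (2 mm), medium
(3–4 mm) and coarse (5–6 mm).

The SSF→σ mapping is `σ_mm = SSF / (2√2)`, from the fact that an LoG
filter's blob response peaks when the blob radius is `σ√2`, i.e. blob
diameter ≈ SSF. Commercial filtration-histogram implementations do not
publish their constant, so this mapping is a documented convention and is
exposed in `FiltrationConfig.sigma_convention`; **absolute feature values
and published cut-offs do not transfer between conventions**, only
directions and orderings do.

Kernel construction (`build_log_kernel`): per-axis `σ_px = σ_mm / spacing`,
square support of half-width `ceil(4·max σ_px)`, the analytic LoG sampled
*without* the `1/(2πσ²)` Gaussian normalisation — equivalent to the
γ=2 scale-normalised LoG `σ²∇²G` used for scale selection, which is what
makes the response of a matched structure peak at its own scale rather
than always at the finest filter — then negated (bright blobs → positive
response, so MPP reads as "mean brightness of highlighted structures") and
mean-subtracted so the coefficients sum to zero exactly. Boundary handling
is mirror padding (the edge-inclusive 'reflect' mode); lesions sit in the
slice interior so this choice is second-order.

Whole slices are filtered before the mask is applied (never mask-cropped
images), so the filter support sees the true surrounding tissue and no
artificial mask-edge ringing enters. One consequence worth knowing: a
lesion whose mean HU differs from its surround produces a genuine edge
response inside the VOI at coarse scales — that is signal, not artifact.

### Features

All mask voxels of a lesion are pooled across slices into one sample per
SSF (volumetric pooling; a per-slice observation mode exists but makes no
claim of equivalence). Features of a sample `x₁…x_n`:

| feature | definition | undefined when |
|---|---|---|
| mean | arithmetic mean | — |
| sd | sample SD, `n−1` denominator (0 if n = 1) | — |
| entropy | Shannon entropy (bits) of the 256-equal-width-bin histogram over `[min, max]`; 0 for constant samples | — |
| skewness | `m₃/m₂^{3/2}` (biased moment ratio) | zero variance |
| kurtosis | excess, `m₄/m₂² − 3` (normal → 0) | zero variance |
| MPP | mean of strictly positive values | no positive values |

Undefined features are explicit missing values (NaN, empty CSV fields),
never zero. Excess kurtosis is used because dichotomisation thresholds
near 0 for kurtosis only make sense on the excess scale. Binning, the SD
denominator and the entropy base are frozen defaults exposed in
`FiltrationConfig`.

## Survival statistics

- **ROC/AUC** (`roc_analysis`): AUC by the Mann–Whitney rank identity with
  half credit for ties; if the raw AUC < 0.5 the direction flips ("low
  values indicate the positive class") and the reported AUC is ≥ 0.5. The
  operating cut-off maximises Youden's J over observed values (prediction
  rule "≤ cut-off" for the low direction, "> cut-off" for high), ties
  broken toward higher specificity. The p-value against AUC = 0.5 uses the
  normal approximation to Mann–Whitney (tie-corrected), which is adequate
  for univariate screening at small n; DeLong is not implemented.
- **Kaplan–Meier** (`km_estimate`): product-limit estimator (lifelines).
- **Log-rank** (`log_rank`): the standard two-group 1-df chi-square from
  observed-minus-expected events over pooled risk sets, implemented as a
  vectorised risk-table computation because the cut-point search evaluates
  it at every candidate threshold; it is validated against lifelines'
  `logrank_test` in the test suite.
- **Optimal cut-point** (`optimal_cutoff_km`): grid search over midpoints
  of consecutive sorted unique feature values, subjects equal to the
  threshold going to the LOW group; splits leaving either group under 10%
  of the cohort (configurable) are inadmissible. The returned p-value
  minimises over the grid and is therefore anti-conservative; every result
  carries `exploratory=True` and the run report repeats the warning. No
  multiplicity adjustment is applied anywhere, by design. A caution from
  the test suite: when one group is all-events and the other all-censored,
  the chi-square can increase toward extreme admissible splits — minimal-p
  thresholds should be read as hypothesis-generating, never as validated
  cut-offs.
- **Cox** (`cox_univariate`): univariate partial-likelihood fit of the
  continuous feature with Efron tie handling (lifelines). Wald 95% CI
  `exp(β̂ ± 1.96·SE)` and Wald p. A monotone partial likelihood (perfect
  separation) is flagged: `converged=False`, coefficient capped at |β|=50,
  SE/CI/p set missing — never a silently diverging estimate.

## Synthetic cohort generator

The generator emulates a contrast-enhanced-CT lung-lesion cohort just well
enough to exercise every pipeline stage with known truth:

- **Phantom** (`generate_phantom`): spherical (in mm) lesion centred in the
  grid; lesion voxels = mean HU + a stationary Gaussian texture field
  (white noise smoothed to `texture_scale_mm`, rescaled to
  `texture_amplitude_hu` SD) + white acquisition noise; background =
  constant soft-tissue HU + the same white noise. Defaults: 12×40×40 grid
  at 2.5×1.0×1.0 mm, 14 mm lesion, 60/40 HU lesion/background, 3 mm texture
  scale, 5 HU noise. The grid is validated to hold the lesion plus the
  coarsest (SSF 6) kernel support.
- **Outcomes** (`generate_cohort`): per patient, texture parameters are
  drawn uniformly from ranges; the true MPP at the reference SSF (default
  3 mm) is computed by the package's own filtration; overall survival is
  exponential with hazard `h₀·exp(β_MPP·MPP)`. Defaults encode a cohort
  like the motivating clinical setting: `β_MPP = −0.117` (HR 0.89 per MPP
  unit), `h₀ = 1.6/day` so a mid-scale patient (MPP ≈ 55) has median OS
  ≈ 270 days, amplitude range 25–60 HU so true MPP spans ≈ 40–100 centred
  in the mid-50s, censoring target 0.57 (roughly 4 in 10 die during
  follow-up), PFS = 0.44 × OS with shared administrative censoring, and a
  180-day landmark for the binary progression label (≈ 43% progressors).
- **Censoring**: independent exponential censoring whose rate is solved by
  bisection so the *expected* censored fraction over the realised hazards
  equals the target; the realised fraction is then within sampling noise
  (±0.1 at n ≥ 200 is asserted in tests).
- **Reproducibility**: per-patient substreams are seeded with
  `(cohort seed, patient index, stage)`, so cohorts are bit-reproducible
  and individual patients are stable under cohort resizing.

What the generator does **not** model — and hence what green tests do not
show about real data: lung anatomy and air-tissue interfaces, respiratory
motion, scanner/reconstruction-kernel effects, inter-observer segmentation
variability, non-proportional hazards, and any biological linkage between
texture and outcome (the MPP–hazard link is imposed, not emergent). The
PFS–OS coupling is a fixed ratio, not a multistate process: it guarantees
ordered, correlated endpoints, nothing more.

## Pipeline

`run_all` = simulate (or load volumes/masks/survival) → extract one row per
(patient, SSF) with per-patient failure isolation → stage-1 ROC screen of
all feature×SSF combinations against the progression label (default screen:
p < 0.05) → stage-2 optimal-threshold KM (OS and PFS) and univariate Cox
(OS) for screened features. Reports are JSON with a provenance block
(config hash, seed, version) and no timestamps, so identical configs give
byte-identical reports; the ROC table always has one row per feature×SSF,
with excluded rows carrying an explicit reason.

## Numerical and design notes

- Filtering uses `scipy.ndimage.correlate`; correlation equals convolution
  here because the kernel is 180°-symmetric. A whole lesion's slices are
  filtered in one 3D call with a (1, k, k) kernel, which is exactly
  per-slice filtering.
- Problem sizes in the test suite (e.g. 12×40×40 phantoms, cohorts of
  30–200, 50 pipeline replicates, 200 Cox recovery replicates) were chosen
  as the smallest sizes at which the asserted statistical properties are
  stable; the generator scales to larger grids and cohorts unchanged.
- Feature tables round-trip losslessly through CSV (shortest-round-trip
  float formatting); volumes round-trip through NIfTI as float64. The DICOM
  writer stores int16 HU (standard CT representation), so sub-HU precision
  is intentionally not preserved on that path.
- `pfs_days ≤ os_days` is validated on every survival table; times are
  non-negative; event flags strictly binary.

## Known limitations

- The SSF→σ constant is a convention; comparisons with other
  implementations must be rank-based, not absolute.
- The AUC p-value is asymptotic; at very small n (< ~10 per class) an exact
  Mann–Whitney test would be preferable.
- The cut-point search reports unadjusted minimal p-values (labelled
  exploratory); permutation-adjusted cut-point inference is deliberately
  out of scope.
- 2D in-plane filtration only; anisotropic voxels are handled via per-axis
  σ in pixels, but no 3D LoG is offered.
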