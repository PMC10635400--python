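# Methods

This note documents the models, algorithms and default choices behind
`cspws`, in the order the pipeline runs them.

## Chromatin autocorrelation model

Within a packing domain the macromolecular density fluctuation `ρ(r)` is
modeled as a stationary, isotropic, zero-mean Gaussian random field whose
autocorrelation function is a truncated power law anchored at the inner
length scale:

```
B(r) = σ_n²                                 r ≤ r_min
B(r) = σ_n² (r / r_min)^(D−3)               r_min ≤ r ≤ r_max
B(r) = B(r_max) · exp(−(r − r_max)/r_max)   r > r_max
```

with defaults `r_min = 23 nm`, `r_max = 334 nm` (the instrument's
sensitivity band) and `σ_n² = 10⁻³`.  This is the minimal family consistent
with the defining relation `D − 3 = ∂log B/∂log r` on the band; the
exponential rolloff keeps the covariance integrable, and the spectrum of
the truncated family can be slightly indefinite, so every consumer clips
the transform at zero (see Simulator below).  Chromatin volume
concentration `φ` and domain genomic size `N_f` ride along as provenance:
they modulate the fluctuation amplitude upstream of `σ_n²` and are not
estimated per pixel.

## Forward model: Σ(D)

A pixel's interference spectrum is modeled in the first Born approximation
as the cosine transform of its axial refractive-index column over the depth
of field `L ≈ 3 µm`:

```
s(λ) = c₀ ∫₀^L α ρ(x, y, z) cos(4π n_media z / λ) dz,      c₀ = 1/L
```

`Σ` is the population standard deviation of `s` across the 101 wavelengths.
Writing the discretized integral as `s = A ρ` and removing the spectral
mean (`P = I − 11ᵀ/N_λ`), the expected spectral variance is the quadratic
form

```
E[Σ²] = (c₀ α Δz)² · tr(P A C_B Aᵀ P),     C_B[i,j] = B(|z_i − z_j|)
```

evaluated with the same axial step `Δz = 10 nm` the simulator uses.
Equivalently `E[Σ²] = C ∫ B(r) T(r) dr` where `T(r)` is the lag-domain
*interference transfer window* derived from the wavelength grid, `n_media`
and `L` (`cspws.optics.transfer_window` returns it).  Two idealized window
modes (`flat`, `raised_cosine` on `[r_min, r_max]`) are kept for analytic
checks; note their orientation differs: a positive band window makes Σ
*increase* with D, while the true interference kernel applied to the
inner-scale-anchored ACF makes Σ *decrease* with D (raising D moves
spectral power below the band probed by the 500–700 nm backscattering
geometry).  The look-up table records its orientation and the inversion
handles both.

Because a single pixel's `Σ²` is a quadratic form in a Gaussian column with
only ~8 effective degrees of freedom (the band–depth product), `Σ` is a
noisy statistic.  `forward_sigma` therefore reports, by moment matching to
a scaled chi-square (Welch–Satterthwaite), the *expected per-pixel Σ*
(`statistic="mean"`, default) rather than `sqrt(E[Σ²])` (`"rms"`); a
geometric-mean option exists as well.

## Inversion: the Σ→D look-up table

`build_lut` tabulates `Σ(D)` on a grid (default 1.5–3.0, step 0.01),
asserts strict monotonicity, and inverts by linear interpolation with
clamping flags at the grid ends.  Beyond D ≈ 3.05 the band signal turns
non-monotone, so grids are confined below that point.

**Per-pixel calibration.**  Plain inversion of a noisy per-pixel Σ through
a curved map is biased (severely so at low D, where the curve flattens).
Mirroring the instrument's own simulation-calibrated estimation framework,
`build_lut(calibrate=True)` constructs a monotone estimator `g(Σ)` solving

```
E[ g(Σ) | D ] = D        for all D in [1.8, 3.0]
```

where the conditional distribution of Σ follows from the eigenvalues of
the interference quadratic form, sampled with a fixed internal seed so the
construction is deterministic.  `g` is piecewise linear on quantile-placed
Σ nodes, constrained monotone through a nonnegative-increment
parameterization and fit by bounded least squares with a small ridge
penalty (residual calibration error < 0.005 in D).  Two consequences are
deliberate:

* the estimator's output range extends past the physical ceiling `D = 3`
  (individual pixels are estimates, not physical values; nuclear averages
  stay unbiased), and
* `nuclear_average_d` includes clamped pixels by default — unbiasedness
  holds over the full output distribution, boundary mass included.  The
  clamped fraction is always reported as a QC metric, and exclusion is
  available by flag.

The uncalibrated LUT retains the exact noiseless round-trip identity
`sigma_to_d(forward_sigma(D)) = D` and is what `build_lut` returns by
default.

**Noise.**  Additive detection noise is removed in quadrature before
inversion, `σ_c = √max(σ² − floor², 0)`; the floor is estimated from
blank-region pixels (`estimate_noise_floor`) or supplied.  With a floor of
20 % of the signal Σ, nuclear-average recovery degrades from ±0.05 to
roughly ±0.10 across D ∈ [2.0, 2.9].

## Simulator

Density fields are synthesized spectrally: evaluate `B` on the periodic
grid (min-image distances), FFT, clip negative spectral values (this is
what guarantees a valid covariance despite the truncation edits to `B`),
color white Gaussian noise, and remove the realized mean.  The axial axis
must resolve the inner scale (`Δz ≤ r_min/2`) and span `≥ 2 r_max`;
transverse axes may be sampled at one column per coherence area
(458 × 458 nm²), since transverse coherence mixing is omitted and each
pixel integrates only its own column.  Two structural facts worth knowing:

* a zero-mean periodic field's sample ACF estimates `B(r) − mean(B)` over
  the grid; `empirical_acf_radial` adds the exact offset back when the
  field carries its target parameters, and
* wrap-around covariance at half the axial period is < 1 % of `σ_n²` for
  the default rolloff, so no padding is applied.

The spectral-cube simulator applies exactly the discretized forward
integral above plus i.i.d. Gaussian per-band noise, and stamps the cube
with the optics and `c₀` used, letting `compute_dmap` warn (or error) on
provenance mismatches with the LUT.

## Synthetic cohorts

`gen_cohort` draws, per patient, a true D from the group's
Normal(mean, sd_between), cell values Normal(true D, sd_within), and
demographics (age, sex, smoking, drinking) from group-level settings.
Defaults: `sd_between = sd_within = 0.05`, 40 cells/patient (the pipeline
enforces the > 30-cells floor downstream), control age 57 ± 8 vs case
62 ± 8, 49 %/48 % female, and an optional linear age effect on D
(−0.008 per year, off by default).  Within- and between-patient variances
are not published for the real cohort; these are round placeholder
magnitudes chosen so patient means vary at the percent level of D.

`two_group_spec(shift)` offsets the case mean by
`shift · √(sd_between² + sd_within²/n_cells)` so the *patient-level
standardized difference* (Cohen's d on patient means) targets `shift`.
For power experiments the realized effect must match the nominal one, so
patient true-D values are drawn as randomly permuted stratified normal
quantiles (`stratify_patients=True`): group means and sds match their
nominal values while cells stay i.i.d.  Without this, the realized effect
size of a 60+60 cohort fluctuates with sd ≈ 0.2 and any power threshold
becomes a coin flip.

**Nucleus images.**  The classifier's preprocessing min-max normalizes
each nucleus, which removes the absolute D level from the image.  Real
csPWS D maps carry D in their spatial statistics (higher D ⇒ larger,
coarser packing domains), so `gen_nucleus_image` encodes a cell's D in a
normalization-invariant signature: the texture correlation length grows
linearly with D (`1.8 + 6·(D − 2.55)` px on a 32-px nucleus).  Passing
classifier tests therefore demonstrate that the pipeline recovers a
texture-coded D signal through preprocessing, feature learning and
patient-level CV — not that real chromatin texture looks like smoothed
Gaussian noise.

## 5-year CRC risk model

Annual rates (advanced-adenoma incidence; AA→CRC progression; metachronous
CRC) are tabulated by history category (`no_history`, `low_risk`,
`high_risk`), sex, and age stratum (< 80 / ≥ 80), converted to cumulative
probabilities by `1 − exp(−rate · t)` with `t = 5 yr`, and combined as

```
CRC_risk = (AAr · Σᵢ AA→CRCᵢ + Nc · CRCm) / (Na + Nc)
```

Patients with a cancer history form the `Nc` pool (metachronous pathway);
all others form the `Na` pool with per-patient AA→CRC terms from their own
stratum.  `AAr` is the group mean of per-patient cumulative AA incidence,
with one override: a patient who *currently* harbors an advanced adenoma
takes `AAr = 1` (the adenoma already exists; only progression risk
remains).  This is what separates the five history/diagnosis groups into
distinct risks with the monotone ordering the regression structure needs.
The shipped rate table contains clearly labeled **placeholder** values
(ordering high ≥ low ≥ none, mild male and ≥ 80 elevation); substitute
published surveillance rates for any real use.  Formula outputs above 1
are clipped with a warning rather than rejected, since the expression is
not itself probability-bounded.

## Cohort statistics

Patient means (not cells) are the unit of inference.  Group comparisons
use Welch's t-test (Mann–Whitney by option) and pooled-sd Cohen's d,
positive when the second group is larger; identical degenerate groups
return d = 0, p = 1, and a mean difference atop zero pooled sd is capped
(default ±20).  No multiplicity adjustment is applied by default (Holm by
flag).  The covariate screen is ordinary least squares via a formula
interface, with an explicit collinearity error listing degenerate columns.
`regress_d_vs_risk` fits group mean D on modeled 5-year risk and reports
slope, intercept and r².  `lesion_size_report` reproduces screening-table
arithmetic: per-category percentages at one decimal and the combined
under-1.5 cm fraction.

## Classifier

* **Segmentation** — supplied label masks are used directly (the study
  outlined nuclei manually); without one, an automated stand-in runs Otsu
  thresholding, hole filling, connected components and a 100-px minimum
  area.
* **Preprocessing** — per-nucleus min-max to [0, 1], background zero-fill,
  bilinear resize (224×224 contract for pretrained-style extractors; the
  default extractor works at 32×32), final rescale to [0, 1].  Constant
  nuclei map to zeros by convention.
* **Features** — the default extractor is a fixed-seed bank of 120
  zero-mean unit-norm 5×5 random convolution filters (4 response
  statistics each) plus a 24-bin histogram and 8 global statistics:
  512 deterministic features, no downloaded weights.  Any object with
  `extractor_id`, `n_features`, `input_size` and `__call__` can be plugged
  in, e.g. a pretrained convolutional network with global average pooling.
* **Autoencoder** — fully connected 512→256→64→256→512, tanh hidden
  layers, linear code/output, Adam on standardized inputs (float32),
  early stopping after 10 stale epochs, training subsampled to at most
  1024 rows for the repeated-CV loop.  Seeded end to end.
* **Random forest** — inner 3-fold, group-aware, label-stratified grid
  search scored by ROC AUC.  `fit_classifier` defaults to the full grid
  {100/300 trees} × {depth ∞/5/10} × {leaf 1/5}; inside
  `cross_validate` the default is the reduced grid {100 trees} ×
  {depth ∞/5/10} × {leaf 1/5} with the sweep scored on a seeded
  group-stratified subsample of ≤ 1200 nuclei and the winner refit on all
  rows — the full sweep refit 20 times would dominate the protocol's
  runtime while changing nothing on separable synthetic data.  Both knobs
  are arguments.
* **Cross-validation** — repeated stratified 4-fold × 5 repeats, split at
  the *patient* level (all nuclei of a patient share a fold; asserted
  structurally).  Per fold the autoencoder and forest are fit on training
  patients only; test-nucleus probabilities are averaged into a patient
  score; AUC, and sensitivity/specificity at the cut-point maximizing
  TP + TN (ties resolved toward the lowest threshold, favoring
  sensitivity), are computed on patient scores.  Summaries are mean ± sd
  over the 20 fold results.  `evaluate_endpoints` reruns the protocol per
  diagnostic endpoint and per lesion-size subgroup, reporting subgroup
  sensitivity at a fixed specificity (default 0.88).

A note on power: with a patient-level standardized shift of 1.5, the
ideal-observer AUC is Φ(1.5/√2) ≈ 0.855 — no classifier can exceed it on
average.  The pipeline operates within a few thousandths of that ceiling
on the stratified synthetic cohorts; single label permutations retain
overlap noise of a few hundredths of AUC around 0.5, so null experiments
at one permutation should be read with that granularity.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` use: 64×64-pixel cubes with 101
bands and 300 axial samples; LUT grids of 151 points; calibration with
4000 fixed-seed chi-square draws and rank-40 eigenvalue truncation; 50
replicate cohorts of 50+50 patients for effect-size recovery; a five-group
risk cohort of 20 patients/group; and a 60+60-patient, 40-cells-each
cohort for classifier power (null at 2 CV repeats, power at 5).  Every
stochastic step takes an explicit seed; repeated runs are bitwise
identical, including fold assignments and cut-points.

## Known limitations

* The forward model is first-Born and scalar, with the glass interface,
  Fresnel coefficients and NA-dependent collection efficiency absorbed
  into one amplitude constant; it is a documented stand-in, not a
  reconstruction of the instrument's FDTD-calibrated framework.
* Transverse coherence mixing is omitted (one axial column per pixel), so
  within-pixel speckle statistics are cruder than in a full 3D vectorial
  treatment.
* The risk table ships placeholder rates; cohort risks are structurally
  meaningful (orderings, regression) but not clinically calibrated.
* Synthetic nucleus texture is smoothed Gaussian noise with a D-dependent
  correlation length — adequate for testing the pipeline's plumbing and
  information flow, silent on real chromatin morphology.
* Sensitivities/specificities and AUCs quoted anywhere in this repository
  are properties of the synthetic study conditions, not of patients.
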