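# Methods

## Signal models and conventions

All models act on trace (direction-averaged) DWI magnitude signals. Units are
the clinical convention: b in mm⁻² s, diffusion coefficients in mm² s⁻¹, so
every exponent is dimensionless. Signals are strictly positive and equal S₀ at
b = 0; for the stretched exponential, 0^α is defined as 0 (the continuity
limit) so the b = 0 anchor holds for every α in (0, 1].

The kurtosis model deserves a note. `dwirep` fits, by default, the exponent

    −b·DDC_K + (1/6)·K²·b²          (form = "as_printed")

in which the kurtosis parameter enters squared. This differs from the common
diffusion-kurtosis expansion −b·D + (1/6)·K·b²·D², which is available as
`form="standard"`. The two forms imply different scales and units for K and
are not interconvertible by a constant factor; the form in force is recorded in
every fit result, parameter-map sidecar and run manifest, and the K-bounds
differ per form ([0, 5×10⁻³] as-printed, [0, 3] standard). The default was
chosen so that fitted K values attach to the same quantity whose repeatability
behaviour this analysis characterises; users wanting conventional DKI
parameters should select the standard form explicitly rather than reinterpret
as-printed values.

With as-printed kurtosis the exponent's derivative changes sign at
b = 3·DDC_K/K², beyond which the modelled signal turns upward; at the default
parameter scale this lies above the largest acquired b, and the monotonicity
property is only asserted below that turning point.

## Voxel-wise estimation

**Bounded NLLS (default).** Trust-region-reflective least squares with
analytic Jacobians. Default bounds: S₀ ∈ (0, 10 × max observed signal];
ADC, D, DDC_α, DDC_K ∈ [10⁻⁶, 10⁻²] mm² s⁻¹; D* ∈ [3×10⁻³, 0.5] mm² s⁻¹;
f ∈ [0, 1]; α ∈ [0.01, 1]; all overridable per fit. Initialization is
model-specific: a log-linear regression seeds S₀ and the decay coefficient;
IVIM is staged (mono fit on b ≥ 300 gives D and the extrapolated intercept,
the intercept ratio gives f, and a 25-point geometric grid seeds D* before the
joint refinement). Estimates pinned at a bound are flagged (`clipped_params`)
rather than silently accepted; an IVIM solution with D* < D (possible because
the D and D* boxes overlap) is clipped to D* = D and flagged. Signals ≤ 0 are
excluded from the fit for log-safety of the initializers, with the count
recorded; a voxel with fewer usable points than free parameters + 1 yields a
flagged non-converged result with NaN parameters, never an exception.

**Adaptive Metropolis–Hastings.** A Gaussian likelihood
exp(−RSS/2σ²) with uniform priors on the fit bounds, sampled with a
symmetric Gaussian proposal. The chain starts at the NLLS solution; proposal
scales initialize from the Gauss–Newton covariance there and adapt in blocks
during burn-in toward ~30% acceptance (acceptance outside [0.05, 0.8] raises a
diagnostic warning flag). The noise scale σ defaults to the NLLS residual
estimate √(RSS/(n−p)) and can be fixed in the config. Defaults: 5,000
iterations, 1,000 burn-in, posterior-median point estimate (posterior mean and
lowest-RSS sample are options). Identical (signal, config, seed) gives an
identical result; ROI fits derive each voxel's seed from (config seed, flat
voxel index) so results are independent of voxel iteration order. The
Gaussian likelihood is a deliberate least-squares reading of the estimation
problem even though magnitude-MRI noise is Rician; at the SNRs of interest the
discrepancy is small relative to the parameter dispersion, and a Rician
likelihood was considered out of scope for the default path.

## ROI histograms

Voxel values are pooled from at most three mask-bearing slices — those nearest
the mask's voxel-count centre of mass along the slice axis, ties broken toward
the inferior slice; masks with fewer slices are pooled in full and the slice
count recorded. NaN voxels (failed fits) are dropped with a logged warning.
Centiles 0–100 use linear interpolation between order statistics (numpy's
default, Hyndman–Fan type 7); the 0th/100th centiles are exactly the sample
min/max and the 50th is the median reused by all downstream statistics. The
quantile rule is fixed rather than configurable: comparing centile tables
computed under different rules would silently bias CV profiles at the extremes.

## Repeatability statistics

For paired per-subject values (v₁ᵢ, v₂ᵢ), dᵢ = ln v₂ᵢ − ln v₁ᵢ and

    CV = 100% × √(exp(σ²/2) − 1),

with σ² the **mean-subtracted** sample variance of {dᵢ} (n−1 denominator) by
default. A zero-mean convention (Σdᵢ²/n) is provided as an option: under the
default, a systematic multiplicative shift between visits is absorbed by the
mean and yields CV = 0, whereas the zero-mean form counts it as disagreement.
Which convention a given published CV used is often not recoverable; both are
exposed and the one in force is recorded in every result row. Natural
logarithms throughout. `expm1` is used so small σ² maps to CV without
cancellation.

The 95% CI uses the chi-square pivot for a normal-theory variance —
df·σ̂²/χ²₍α/2₎ bounds mapped through the CV formula (df = n−1 mean-subtracted,
n zero-mean) — which is exact when the log-differences are normal, as they are
by construction in the phantom; a percentile bootstrap is available for data
where normality is doubtful. Centiles at which any subject has a non-positive
value (possible for f, α or K pinned near 0) are skipped with a warning and
counted in the run manifest rather than propagating log-domain errors.

Paired t-tests compare the per-subject visit medians on the raw scale. When
the paired differences have exactly zero variance the t statistic is
degenerate; such cases are reported as t = 0, p = 1 with a `degenerate` flag
(this includes a constant non-zero shift, where a textbook t would be ±∞ —
flagging was preferred over emitting infinities into report tables).
Correlations are Pearson ρ of the visit-averaged medians across subjects;
parameters constant across the cohort yield NaN off-diagonal entries.

## Synthetic paired-visit phantoms

Each synthetic subject is an elliptical "tumour" ROI over three central slices
of a small 3-D grid. Voxel-wise parameters are drawn per subject:

* diffusion coefficients: log-normal, median 1.35×10⁻³ mm² s⁻¹ (D, ADC),
  1.5×10⁻³ (DDC_α), 1.78×10⁻³ (DDC_K), log-sd 0.25 — solid-tumour scale with
  ~25% intra-ROI heterogeneity;
* f: log-normal median 0.09 (log-sd 0.30, capped at 0.6); D*: log-normal
  median 1.3×10⁻² mm² s⁻¹; α: normal 0.90 ± 0.05 truncated to (0.3, 1];
  K: log-normal median 1.3×10⁻³ (as-printed scale);
* S₀ constant at 1000 a.u.

A per-subject multiplicative factor exp(N(0, 0.35²)) scatters each parameter's
location, giving the between-patient spread a mixed tumour cohort shows.

**Test–retest convention.** Each visit's parameters are the subject's base
field multiplied by an independent factor exp(ε), ε ~ N(0, retest_log_sd²),
drawn per subject-parameter (or per voxel, as an option). The log-difference
between visits then has variance exactly 2·retest_log_sd², so the injected CV
is analytically

    CV_expected = 100 × √(exp(retest_log_sd²) − 1),

which is what the coverage and flat-profile validations check against. The
default retest_log_sd = 0.025 injects a ~2.5% CV, the scale of the best
clinically reported diffusion-coefficient repeatability. Perturbing both
visits (rather than visit 2 only) keeps the generator symmetric under visit
exchange, matching the visit symmetry of the CV statistic itself. Note that
clipping bounded parameters (α at 1, f at its cap) after perturbation slightly
deflates their realized CV near the limits — the same edge effect imposed fit
bounds produce in real analyses.

**Noise.** Rician by default: √((S+n₁)² + n₂²) with independent N(0, σ²)
channels, σ = S₀/SNR, applied to the whole volume (background becomes
Rayleigh). SNR is defined at b = 0 on the generated trace volume and defaults
to 50 — a package choice for a plausible clinical trace image, not a measured
value. Gaussian noise is available for analytic checks (its mean is exactly
the clean signal, unlike Rician).

**What the phantom does not emulate:** EPI distortion, motion between b-values
or visits, eddy currents, partial-volume mixtures at the ROI rim, necrotic
exclusions, spatially correlated noise, or ROI re-drawing variability between
visits. Passing validations therefore demonstrate the correctness and
statistical calibration of the *analysis chain*, not that clinical data will
achieve the same CVs: real repeatability includes repositioning and
delineation variance the generator deliberately holds fixed (both visits share
one mask).

## Validation design and problem sizes

The test suite validates: exact reduction identities (IVIM f=0, stretched α=1,
kurtosis K=0 all collapse to the monoexponential at machine precision);
agreement of the CV statistic with an independent textbook implementation at
10⁻¹² relative over 1,000 random cohorts; noiseless recovery of all four
models' parameters at the six study b-values to better than 10⁻⁴ relative;
SNR-50 recovery over 1,000 replicate voxels per model; chi-square CI coverage
≈95% for injected CVs of 2/10/40% over 500 cohorts of 15 subjects; the bathtub
CV-vs-centile shape on a fitted 20-subject noisy cohort; cross-model
correlation of diffusion coefficients on a 15-subject mono-field cohort
fitted with all four models; and the end-to-end noise-free
null (CV ≡ 0). Cohort grids are kept small (roughly 150–230 ROI voxels per
subject over the three slices) —
enough for stable centile estimates while keeping the full validation suite in
the low minutes on one CPU.

One limitation is worth stating precisely: at SNR 50 with this six-b scheme
and typical tumour parameter values, the Cramér–Rao bound puts the relative
standard deviation of the IVIM slow coefficient D at ~10% and of DDC_K at ~9%
per voxel, i.e. a median absolute relative error of ~6–7% for any unbiased
estimator. The measured NLLS errors (~6%) sit at that information-theoretic
floor; the stretched-exponential DDC_α (~3%) is the only non-mono diffusion
coefficient that resolves below 5% per voxel under these conditions. Both
estimators (NLLS and posterior-median MCMC) were checked and perform
equivalently here. Voxel-level error at fixed SNR should not be confused with
cohort-level median CV, which benefits from pooling hundreds of voxels and is
~2–6% for all diffusion coefficients in the same simulations.

## Numerical and degenerate-input choices

* NLLS tolerances 10⁻¹² (xtol/ftol/gtol), max 600 evaluations, parameters
  scaled by their initial magnitudes so mm² s⁻¹-scale coefficients and
  1000-scale S₀ condition equally.
* A constant (flat) signal drives the decay coefficient to its lower bound,
  reported with the clipped flag and S₀ equal to the signal level.
* σ² > 1400 (log-scale variance overflow) reports CV = ∞ rather than raising.
* Empty masks, missing b-values, ambiguous file-to-b associations, non-binary
  masks and geometry mismatches are descriptive errors; per-voxel fit failures
  are counted, not fatal.
* Determinism: phantom generation, NLLS fitting and the full pipeline are
  bit-reproducible given (config, seed); MCMC is reproducible given the seed.
  Manifest files record config hashes, seeds, package versions and warning
  counts for every run.
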