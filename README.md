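# dwirep

Test–retest repeatability analysis of non-Gaussian diffusion-MRI models.

`dwirep` is for imaging scientists who fit advanced diffusion models to
multi-b-value diffusion-weighted MRI (DWI) of tumours and need to know which
derived parameters — and which parts of their ROI histograms — are actually
repeatable between visits. It implements the complete analysis chain: voxel-wise
model fitting, ROI histogram centile tables, and repeated-measures
coefficient-of-variation (CV) statistics over paired (test–retest) visits,
together with a synthetic paired-visit phantom generator used to validate every
stage against known ground truth.

## Models and statistics

Four signal models are fitted voxel-by-voxel to the decay over diffusion
weightings *b* (mm⁻² s; default scheme 0, 50, 100, 300, 600, 1000):

| model | signal equation | parameters |
|---|---|---|
| monoexponential | S_b = S₀·exp(−b·ADC) | ADC (ADC₁₀₀ when restricted to b ≥ 100) |
| IVIM (bi-exponential) | S_b = S₀·[f·exp(−b·D*) + (1−f)·exp(−b·D)] | f, D, D*, and f·D* |
| stretched exponential | S_b = S₀·exp(−(b·DDC_α)^α) | DDC_α, α |
| kurtosis | S_b = S₀·exp(−b·DDC_K + K²b²/6) | DDC_K, K |

Estimation is bounded nonlinear least squares by default, or an adaptive
Metropolis–Hastings sampler (Gaussian likelihood, uniform-on-bounds priors,
posterior-median point estimate) as a robust alternative.

Per subject, visit and parameter, in-mask voxels from the three central ROI
slices are pooled and the 0th–100th integer percentiles computed. Repeatability
at each centile is the repeated-measures coefficient of variation

    CV = 100% × √(exp(σ²/2) − 1)

where σ² is the variance of the paired differences of log-transformed values
across the cohort, with a 95% chi-square confidence interval. Visit medians are
compared by paired t-test, and the Pearson correlation matrix of visit-averaged
medians relates parameters across models.

## Worked example

Simulate a 15-subject paired-visit IVIM phantom cohort (SNR 50 Rician noise,
2.5%-scale injected test–retest variability) and run the full pipeline:

```python
from dwirep import PhantomSpec, PipelineConfig, run_pipeline

spec = PhantomSpec(model_id="ivim", grid_shape=(16, 16, 5), n_subjects=15,
                   snr=50.0, retest_log_sd=0.025, seed=42)
config = PipelineConfig(phantom=spec, outdir="out", seed=42)
bundle = run_pipeline(config)
print(bundle.cv_median_table.round(2).to_string(index=False))
```

which prints (this exact output, given the seed):

```
parameter subgroup  cv_percent  ci_low  ci_high  n_pairs
   ADC100     full        3.96    2.90     6.24       15
        f     full       10.40    7.61    16.47       15
        D     full        4.11    3.01     6.48       15
    Dstar     full       10.71    7.83    16.97       15
   fDstar     full        7.16    5.24    11.31       15
DDC_alpha     full        4.42    3.24     6.98       15
    alpha     full        0.84    0.61     1.32       15
    DDC_K     full        2.94    2.15     4.63       15
        K     full        3.48    2.54     5.48       15
```

Each row is one derived parameter's median-centile CV (%) with its 95% CI over
the 15 paired visits. The diffusion coefficients (ADC₁₀₀, D, DDC_α, DDC_K)
repeat at ~3–4.5%, close to the injected variability, while the
perfusion-related IVIM parameters f and D* are markedly worse even at this
moderate noise level — the ordering seen in clinical repeatability studies.
`bundle.correlations` shows ADC₁₀₀, D, DDC_α and DDC_K correlated at ρ ≥ 0.97
(they all report the same underlying diffusion), while α and DDC_α are nearly
orthogonal. `bundle.cv_by_centile` holds the full CV-vs-centile profiles, which
develop the characteristic "bathtub" shape — flat through the mid-centiles,
rising sharply at the histogram extremes — once fit noise is present.

The same pipeline runs from the shell (`dwirep run --config config.yaml --seed 42
--outdir out`), and each stage is available separately as `dwirep simulate`,
`fit`, `centiles`, `repeatability` and `report`. In data mode
(`input_dir` instead of `phantom`), the pipeline reads NIfTI volume stacks and
ROI masks with a JSON manifest mapping files to visits and b-values.

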