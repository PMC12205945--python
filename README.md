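# twinlocal

Twin-design variance decomposition of **local resting-state fMRI metrics** —
regional homogeneity (ReHo) and the fractional amplitude of low-frequency
fluctuations (fALFF) — across two longitudinal waves.

The package is aimed at researchers studying genetic and environmental
influences on brain function in twin cohorts.  It covers the whole chain:

1. **Metric extraction** from 4D runs: framewise displacement and motion QC,
   Friston-24 confound regression, detrending, scrubbing, ideal bandpass,
   KCC-ReHo (Kendall's W over the 26-neighbor voxel neighborhood), fALFF
   (amplitude-spectrum ratio of 0.01–0.08 Hz to 0–0.25 Hz), Z-scoring,
   masked Gaussian smoothing, atlas ROI means, AP/PA run averaging.
2. **Twin modelling**: saturated bivariate models (assumption and covariate
   LRTs, twin correlations) and bivariate Cholesky ACE/AE/CE/E models fitted
   by full-information maximum likelihood (unpaired twins retained), AIC
   model selection with a ΔAIC < 2 ambiguity flag, tests for new wave-2
   influences (a22 = 0) and (de)amplification (a21 = a11), raw and
   standardized variance components with 95% profile-likelihood CIs, and
   cross-trait genetic/environmental correlations.
3. **Associations**: two-level random-intercept mixed models linking ROI
   metrics to behavioral scores across waves, with multivariate twin
   follow-ups, and Benjamini–Hochberg FDR within pre-declared test families.
4. **Synthetic data** with known ground truth — twin cohorts drawn from
   explicit latent A/C/E factors, and 4D runs with controllable neighborhood
   coherence and low-frequency power — so every stage is testable end to end.

## The model

For one metric measured at waves 1 and 2, each source S ∈ {A, C, E} gets a
lower-triangular path matrix

    S = [[s11,   0],
         [s21, s22]]

The family covariance over (twin1 w1, twin1 w2, twin2 w1, twin2 w2) has
within-twin block `AA' + CC' + EE'` and cross-twin block `k·AA' + CC'`,
k = 1 for MZ and 0.5 for DZ pairs.  Wave-1 heritability is
`h² = a11² / V1`; `a21²/V2` and `a22²/V2` are the continuing and new genetic
shares of wave-2 variance.  Age, sex and mean FD enter the mean structure.
See `docs/methods.md` for the full account.

## Worked example

```python
from twinlocal.synthetic import SimulationConfig, simulate_twin_cohort, \
    truth_from_proportions
from twinlocal.twin import TwinData, fit_cholesky, decompose_variance, profile_ci

cfg = SimulationConfig(
    n_mz_pairs=2000, n_dz_pairs=2000,
    cholesky_truth=truth_from_proportions(h2=0.5, c2=0.2, overlap=0.6),
    beta_age=0.0, beta_sex=0.0, beta_fd=0.0,
    p_missing_wave2=0.0, p_unpaired=0.0, seed=1,
)
df, truth = simulate_twin_cohort(cfg)
fit = fit_cholesky(TwinData.from_long(df), "ACE", n_starts=2, seed=0)
dec = decompose_variance(fit)
lo, hi = profile_ci(fit, "std_a1")
print(f"wave-1 h2 = {dec['std']['A']['w1']:.3f}  (95% CI {lo:.3f}-{hi:.3f})")
print(f"wave-1 c2 = {dec['std']['C']['w1']:.3f}, e2 = {dec['std']['E']['w1']:.3f}")
```

Output:

```
wave-1 h2 = 0.466  (95% CI 0.392-0.541)
wave-1 c2 = 0.220, e2 = 0.314
```

The generating truth (h² = 0.5, c² = 0.2, e² = 0.3) is recovered within
sampling error at 2000 pairs per zygosity, and the profile interval covers it.

## Command line

```bash
twinlocal all --seed 11 --out demo_out          # simulate → metrics → twin → assoc
twinlocal metrics --bold ap.nii.gz pa.nii.gz \
    --motion ap.par pa.par --atlas atlas.nii.gz --tr 0.93 --out table.tsv
```

`twinlocal all` writes `metrics_table.tsv`, `twin_results.tsv` (chosen model,
AIC table, components with CIs, constraint tests), `saturated_tests.tsv`,
`twin_correlations.tsv`, `associations.tsv`, a JSON manifest and a text
summary.  Reruns with the same seed are byte-identical.

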