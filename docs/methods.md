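# Methods

`twinlocal` estimates genetic and environmental contributions to local
resting-state fMRI metrics — regional homogeneity (ReHo) and the fractional
amplitude of low-frequency fluctuations (fALFF) — in a two-wave adolescent
twin design, and provides the synthetic data needed to validate every stage
without access to restricted cohort data.

## The twin model

The classical twin design compares monozygotic (MZ) and dizygotic (DZ)
twin-pair covariances.  Phenotypic variance is decomposed into additive
genetic (A), common/shared environment (C) and unique environment plus
measurement error (E) sources; cross-twin correlations of the latent factors
are fixed at 1 (MZ) / 0.5 (DZ) for A, 1 for C, and 0 for E.  A and C are
identified by the MZ/DZ contrast; dominance (D) models are out of scope
(C and D cannot be estimated together, and distinguishing A from D needs far
larger samples than the design emulated here).

Two measurements per person — wave-1 and wave-2 values of one metric, or two
different traits — are modelled with a bivariate Cholesky parameterization:
per source a lower-triangular path matrix, e.g.

    A = [[a11,   0],
         [a21, a22]]

whose Gram matrix `A A'` is that source's contribution to the within-person
covariance.  The implied 4x4 family covariance over (twin1 wave1, twin1
wave2, twin2 wave1, twin2 wave2) has within-twin block `AA' + CC' + EE'` and
cross-twin block `k AA' + CC'` (k = 1 or 0.5).  This parameterization is
positive semidefinite by construction, which is the reason it was preferred
over direct variance components (those can go negative in small samples).

Interpretation of the wave-2 paths: `a21` carries the wave-1 genetic factor
forward (continuing influence), `a22` is wave-2-specific (new) genetic
variance.  Standardized squared paths (`a21^2 / V2`, `a22^2 / V2`) sum with
the C and E analogues to 1 at each wave.

### Likelihood

Fitting is full-information maximum likelihood (FIML): each family
contributes the multivariate-normal −2 log density of its observed
subvector, so unpaired twins and families missing wave 2 still inform means
and variances.  Families are grouped by (zygosity, missingness pattern); for
groups with a covariate-free mean structure the likelihood is evaluated from
sufficient statistics (mean and scatter), making the cost per evaluation
independent of sample size.

Covariates (age in years, sex coded male = 0 / female = 1, mean framewise
displacement in mm) enter the mean structure with wave-specific slopes
shared across co-twins, estimated jointly with the variance parameters —
not regressed out beforehand.  Internally covariates are standardized
(z-scored) to keep the likelihood surface well conditioned; reported slopes
are mapped back to per-original-unit scale.  This matters in practice:
uncentered age (~11.5 y) and mean FD (~0.19 mm, SD ~0.03) make the
intercept–slope directions nearly collinear and quasi-Newton optimization
crawls.

### Optimization

Quasi-Newton (L-BFGS-B) with numerically approximated gradients, bounds
fixing the sign of diagonal paths (a11, a22, … ≥ 0) to remove reflection
non-identifiability, and multi-start: the first start is moment-based
(derived from sample twin correlations via the classic `2(rMZ − rDZ)`
algebra), the rest jitter it; 5 starts by default, fewer in large-n
harnesses where the surface is effectively unimodal.  Constraint refits
(`a22 = 0`, `a21 = a11`, profile points) warm-start from the unconstrained
optimum.  Convergence uses L-BFGS-B's relative-reduction rule at `ftol`
1e-12 (Cholesky models) / 1e-11 (saturated models).

A near-singular implied covariance (e.g. a candidate point implying a
perfectly correlated pair of waves) returns a large penalized value rather
than an exception, keeping optimizers inside the valid region.  Exactly
duplicated traits therefore cannot be fitted — the optimum lies on the
singular boundary — and validation uses a near-copy with a small
independent-noise admixture instead.

### Saturated models and assumption tests

The saturated model frees 4 means and a full 4x4 covariance per zygosity
(plus shared covariate slopes).  Covariances are parameterized as
`diag(s) R diag(s)` with log-SDs and a row-normalized Cholesky factor for R,
so equality constraints on variances (across birth order or zygosity) reduce
to parameter sharing.  Assumption tests are likelihood-ratio tests of each
constrained saturated model against the full one (df = number of collapsed
parameters, 4 per test here).  Covariate tests drop both waves' slopes of
one covariate (df = 2); covariates are carried into the genetic models
regardless of the outcome.  Twin correlations are read off the saturated MLE
covariance; their intervals use the Fisher-z approximation with the
per-zygosity complete-pair count (an intentional approximation — these are
descriptive quantities).

### Model selection and constraint tests

ACE, AE, CE and E submodels are compared by AIC (`−2lnL + 2k`); minimum AIC
wins, exact ties break toward fewer parameters, and a runner-up within 2 AIC
units raises an ambiguity flag that is carried on every result row.  Tests
for new influences fix `a22 = 0` (or `c22 = 0`); tests for (de)amplification
tie `a21 = a11` (or C analogue) and report the direction of the
unconstrained inequality.  LRT p-values use the standard chi-square
reference with df = number of constraints, which is conservative for the
boundary null `a22 = 0`; a 50:50 chi2(0):chi2(1) mixture is available via
`mixture=True` for sensitivity analysis.  Calibration simulations confirm
the conservatism (null rejection below nominal).

### Profile confidence intervals

Intervals are likelihood-based: a bound is the quantity value at which the
profile deviance (all other free parameters re-optimized) rises by the
chi-square(1) quantile, found by a one-probe quadratic extrapolation and
Brent root refinement with warm-started inner solves (well under the cap of
60 refits per bound).  Standardized proportions are profiled by
reparameterization — the constrained path is derived from the remaining
paths (at wave 2, the pinned magnitude keeps a free direction angle) — which
avoids generic equality-constrained solvers on the hot path; other
quantities (source correlations, raw paths) use SLSQP with an equality
constraint.  Bounds that run into the parameter-space edge (a proportion at
0 or 1) are reported at the edge.  If the profile search fails, a
delta-method Wald interval from a finite-difference Hessian is returned
instead.

Coverage validation profiles the wave-1 genetic proportion, which is
interior to the parameter space in every grid cell of the recovery harness;
a zero-C truth sits on the boundary, where two-sided interval coverage is
not expected to be nominal.

### Cross-trait correlations

For two traits measured on the same occasion, the same bivariate machinery
applies with (trait 1, trait 2) in place of (wave 1, wave 2).  The genetic
correlation is `r_A = a11 a21 / (|a11| sqrt(a21^2 + a22^2))`; C and E are
analogous; the phenotypic correlation comes from the implied within-twin
cross-trait covariance.  Brain–behavior follow-ups reuse this with (ROI
metric, behavior total score) per wave.

## Local metrics

Per run, in order: Power-convention framewise displacement (sum of absolute
translation deltas plus 50 mm times the sum of absolute rotation deltas;
FD of the first volume defined 0) with exclusion of acquisitions whose mean
FD strictly exceeds 0.3 mm; Friston-24 confound regression (6 motion
parameters, their one-volume lags, both squared) by per-voxel OLS with the
voxel mean restored; linear detrending; FD scrubbing at 0.5 mm with 1
volume back / 2 forward censored and censored volumes removed before
ranking/spectra.  Mean FD is computed before scrubbing over all retained
volumes.  DVARS-based censoring is not implemented (no DVARS inputs are
defined in this pipeline).

- **ReHo**: Kendall's coefficient of concordance W of each in-mask voxel
  with its 3x3x3 neighborhood (K ≤ 27 in-mask voxels), computed on
  band-passed data (ideal DFT filter keeping 0.01 ≤ f ≤ 0.08 Hz, DC
  removed, band edges inclusive).  Temporal ranks use midranks for ties; no
  tie-correction term in the denominator by default (matching common
  neuroimaging practice; `tie_correction=True` adds it).  Voxels with fewer
  than 2 in-mask neighbors are missing.
- **fALFF**: ratio of the amplitude spectrum (square-rooted periodogram;
  `mode="power"` switches to raw power) summed over 0.01–0.08 Hz to the sum
  over 0 < f ≤ 0.25 Hz, computed on detrended, *not* band-passed data.
  Zero-variance voxels are missing.

Maps are Z-standardized within the brain mask (population-SD convention),
then smoothed with a masked 6-mm-FWHM Gaussian (out-of-mask and missing
voxels excluded, kernel weights renormalized), in that order.  ROI means are
taken over atlas labels (missing voxels excluded; empty ROIs missing), the
AP and PA runs are averaged elementwise, and a missing run makes the
subject-wave missing under the default policy.  The pipeline driver asserts
the ordering contract: bandpass before ReHo, never before fALFF.
Coordinates are voxel-space throughout; spatial normalization, segmentation
and slice-timing correction are out of scope (performed upstream by
standard tools on real data).

## Synthetic data

The cohort generator draws the latent A/C/E factors explicitly per family —
two factors per source (one loading on both waves, one wave-2-specific),
each with the source's fixed cross-twin correlation — and maps them through
the Cholesky paths, so the per-individual latent contributions are available
as ground truth for oracle checks.  Covariate effects are added on top: age
is shared within a pair (wave-1 mean 11.5 y, SD 1.3, +1.7 y at wave 2), sex
is Bernoulli(0.5) and forced equal within MZ pairs, mean FD is |N(0.19 mm,
0.06 mm)|.  Default effect sizes (0.01 per year, 0.03 for sex, 1.0 per mm of
FD, i.e. ~0.06 per FD SD) sit in the weak range reported for motion and
demographic effects on local rs-fMRI metrics; they are free parameters of
the generator.  Defaults of 56 MZ / 49 DZ pairs mirror a realistic
adolescent twin cohort; recovery harnesses use thousands of pairs.
Wave-2 missingness is drawn per family (default 25%), and unpaired twins
arise by deleting one co-twin's phenotype while retaining the record
(default 20% of families), matching how such cohorts retain singletons to
stabilize means and variances.

The fMRI generator gives each ROI a shared time series; voxel series are
`sqrt(rho) * shared + sqrt(1 − rho) * noise`, so the expected voxel-pair
correlation equals the coherence target rho.  Shared and noise series have
identical amplitude-spectrum shape — flat at one level inside 0.01–0.08 Hz
and another level in the rest of 0–0.25 Hz, empty above — chosen so the
expected fALFF equals the band-fraction target regardless of rho.  Motion
parameters are Gaussian random walks (rotations scaled by 1/50 so their FD
contribution matches translations).  A coherence target of 1 with zero
noise is rejected as degenerate (all ranks tie).  The generator makes no
attempt at anatomy, physiological noise, or multiband artifacts, so passing
tests demonstrate correctness of the estimators, not robustness to real
acquisition artifacts.

In the end-to-end pipeline, per-individual ROI coherence targets are
themselves drawn from an ACE twin model (base 0.5, SD 0.12, h² = 0.5,
c² = 0.2), so twin structure propagates through the imaging chain to the
extracted metrics.

## Associations

Behavior scores are linked to ROI metrics with a two-level random-intercept
linear mixed model across waves (`behavior ~ roi + age + sex + mean FD +
wave`, wave coded 0/1, random intercepts for family and participant nested
in family, ML fit via statsmodels MixedLM).  The direction of the regression
(behavior on brain) is a convention; the reverse is a one-line change.  The
predictor's p-value is a Wald z test.  A singular nested structure triggers
a documented fallback to the family-only intercept.  Benjamini–Hochberg FDR
is applied within four separate families of tests — covariate effects,
assumption tests, new-influence/(de)amplification tests, and associations —
never across them.

## Pipeline, determinism and problem sizes

All randomness flows from one master seed through a keyed hash-splitting
scheme (`derived_seed(master, *keys)`), result tables are written with a
fixed float format, and the manifest carries the config hash — reruns with
the same seed are byte-identical.

Validation problem sizes were chosen to make Monte-Carlo error small
relative to the tolerances while staying desk-scale: the recovery grid runs
h² ∈ {0.2, 0.5, 0.7} × c² ∈ {0, 0.2} at 2000 pairs per zygosity with 50
replicates per cell; LRT size uses 500 null replicates (power 100); model
selection 100 replicates; the demo pipeline uses 16 MZ + 16 DZ pairs, a
20x20x12 grid, 2 ROIs and 96 volumes.

## Known limitations

- LRT p-values at boundary nulls use the chi-square reference by default
  (conservative); the mixture option is a sensitivity tool, not the default.
- Fisher-z intervals for twin correlations ignore the FIML weighting of
  incomplete pairs.
- The synthetic fMRI model has no spatial autocorrelation beyond ROI
  membership and no physiological confounds.
- Behavioral scores are treated as continuous totals; no item-level or
  ordinal modelling.
- At demo sample sizes (tens of pairs) variance-component estimates and
  their intervals are wide and frequently hit the parameter boundary; the
  demo exercises plumbing and determinism, not inferential precision.
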