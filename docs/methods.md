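# Methods

`neonoci` implements an analysis chain linking individual variability in
neonatal noxious-evoked BOLD responses to (i) resting-state network (RSN)
activity amplitudes, via cross-validated prediction, and (ii) white-matter
microstructure, via an exploratory–confirmatory correlation design.  The
real cohorts such an analysis targets are not distributable, so the package
ships a seeded synthetic-cohort generator whose latent structure matches
the assumptions of every downstream stage; all tests and the acceptance
script run on these simulated cohorts.

## Evoked-response estimation

Each event-related run is fit voxelwise by OLS against a design of (1) the
stimulus boxcar convolved with a double-gamma haemodynamic response
function, (2) an intercept, and (3) demeaned polynomial drift regressors
(default order 1).  The HRF is the difference of two gamma densities with
all five shape parameters configurable; the default is the adult canonical
parameterisation (peak shape 6 / scale 1 s, undershoot shape 16 / scale
1 s, ratio 1/6; peak ≈ 5 s), normalised to unit peak so response scale
lives entirely in the beta.  Neonatal haemodynamics are slower and
shallower than the adult response, so users fitting real neonatal data
should supply an infant parameterisation; nothing downstream depends on
the specific kernel, because the generator and the estimator share it.

Two deliberate simplifications relative to common task-fMRI practice:

* **No temporal prewhitening.**  The GLM is plain OLS.  The synthetic noise
  model keeps temporal autocorrelation mild (AR(1) coefficient 0.3), where
  the efficiency loss from ignoring it is small and point estimates remain
  unbiased.
* **Drift regressors instead of high-pass filtering.**  Filtering is
  treated as preprocessing; slow drift in the generator is exactly linear
  and exactly captured by the default drift term.

The **overall response amplitude** of a subject is the OLS slope of the
subject beta map regressed on the group map (one-sample t-map across
subject betas) over in-mask voxels, with intercept — a per-subject scale
factor relative to the group-average response.  The group map is read as
the regressor and the subject map as the data; this choice yields
amplitudes in "multiples of the group response" and is affine-equivariant
in the subject map.  Zero-variance voxels in the group t-map are set to 0
with a warning rather than raising, since phantom edges routinely produce
them.

**Cluster inference** is one-sample sign-flip permutation: the statistic is
a pseudo-t whose denominator variance map is Gaussian-smoothed (default
FWHM 6 mm, mask-normalised) to stabilise low-df variance estimates; each
voxel's pseudo-t is mapped to a z-score through its own permutation-null
rank (self-excluded, clipped at 1/(2B) so the top rank stays finite);
clusters form at z ≥ Φ⁻¹(1−p) with 26-connectivity; the cluster statistic
is voxel count; family-wise error p is the fraction of permutations whose
maximum cluster size reaches the observed size.  With n subjects the null
is enumerated exhaustively whenever 2ⁿ does not exceed the permutation
budget, and p-values are then exact multiples of 2⁻ⁿ.

**Template expression** is spatial Pearson correlation (demeaned) or
cosine similarity (not demeaned, retaining magnitude — used for adult
pain-signature response scores).  Group-level expression is tested by a
sign-flip one-sample t-test; between-subject association with amplitudes
by a permutation Pearson test.  Family-level correction divides alpha by
an effective number of tests estimated from the family's correlation
matrix, with both the eigenvalue-fraction estimator (applied to the
absolute correlation matrix) and the eigenvalue-variance estimator
available.

## Permutation p-value conventions

Exhaustive nulls report p = c/total with the identity permutation included
in the count; Monte-Carlo nulls report p = (1+c)/(1+B).  Both conventions
are recorded on every result object.  Monte-Carlo p-values are therefore
never 0 and the attainable minimum is 1/(B+1).

## Resting-state amplitudes

Network timeseries come from the spatial stage of dual regression: each
frame's in-mask voxel vector is regressed on the K network template maps
plus a per-frame intercept.  The intercept prevents the global signal
level from leaking into network coefficients.  Amplitude is the median
absolute deviation from the median (MAD) of the network timeseries,
unscaled (no 1.4826 consistency factor) — amplitudes are in raw MAD units.
Outlier content is the fraction of frames beyond k·MAD from the median
(default k = 5, falling back to the standard deviation for MAD = 0); this
is an explicit stand-in metric, defined here because robust spike metrics
vary across pipelines.  Template sets from two datasets are matched by
greedy descending-|r| one-to-one assignment with a minimum |r| guard
(default 0.3) — a numeric surrogate for correlation-plus-visual matching.

## Confounds

Framewise displacement is the sum of absolute backward differences of the
six rigid parameters, rotations converted to arc length on a 50 mm sphere
(radius configurable); FD of frame 1 is 0 and the mean excludes it.
Stimulus-correlated motion is the multiple correlation R between the
predicted BOLD response and the 24-column motion expansion (parameters,
backward-difference derivatives, both squared).  Reference-region
amplitudes are the mean stimulus beta over the region (event-related runs)
or the MAD of the region-mean timeseries (resting runs; the region is
averaged voxelwise first).

## Amplitude prediction

The estimator is a linear support vector regression (epsilon-insensitive
loss, epsilon 0.1; L2/ridge penalty with strength grid {0.001, 0.01, 0.1,
1}) evaluated by leave-one-out cross-validation.  Design choices where the
procedure is genuinely open:

* **Cross-validated confound regression.**  Features and response are
  residualised on their confound sets with coefficients estimated on
  training rows only, applied to the held-out row.  Permutation inference
  shuffles the *raw* response before adjustment and reruns the entire
  pipeline, so the null preserves the confound structure (the alternative,
  shuffling the adjusted response, is available via configuration).
* **Per-fold feature standardisation** on training statistics, so the
  ridge penalty is scale-comparable across network amplitudes.
* **Inner model selection**: LOO grid search minimising MSE on the outer
  fold's adjusted, standardised training data, ties broken toward the
  smallest C (stronger regularisation).  The confound adjustment is not
  re-fit per inner split; the inner search is a selection heuristic, not
  an unbiased performance estimate, and the outer loop remains leak-free.
* **Metrics**: sums-of-squares R² (reported as-is, negative allowed),
  RMSE, Spearman rho; identically R² = 1 − n·RMSE²/SS_tot.  Permutation
  tests are one-tailed (≥ for R²/Spearman, ≤ for RMSE).

Model transfer to a new cohort fits once on the full training sample and
scores target features adjusted either within the target sample (default —
appropriate when features/confounds were extracted identically but on a
different scanner/population) or with the training coefficients.

## Structure–function analysis

Tract features are means of diffusion parameter maps (MD, FA, MK) over
tract probability masks thresholded at 0.01, after removing voxels outside
theoretical ranges (MD < 0; FA outside [0,1]; MK outside [0,3]).  The
exploratory screen computes 16×3 = 48 confound-adjusted Pearson
correlations (confounds: diffusion head motion, noisy-voxel count, total
brain volume) against predicted amplitudes, with single-step max-|r|
permutation FWER control: each permutation shuffles the amplitude vector,
re-residualises, recomputes all 48 adjusted correlations and records the
maximum |r|.

The surviving MD tracts are pooled by the first principal component
(MD PC1).  PCA conventions: columns are confound-residualised first, then
standardised (tract MDs share units but differ in level and spread); the
PC1 sign is fixed so the mean loading is positive, making "higher PC1 =
higher MD" and the hypothesised correlation direction well-defined.
Raw-covariance and raw-data modes exist for sensitivity analysis.  The
confirmatory arm reports per-tract correlation polarities and a one-tailed
permutation test of the PC1–amplitude correlation in the hypothesised
direction; subjects with incomplete diffusion data are dropped by row
completeness.  The all-subsets analysis evaluates the squared PC1
correlation for every nonempty subset of the 16 tracts (65,535 subsets,
computed from the eigenstructure of the residualised correlation matrix,
which is algebraically identical to PCA per subset) and reports the target
subset's inclusive percentile.  Cross-dataset consistency is the Pearson
correlation between the two 16-tract MD association profiles.

## Synthetic cohorts

A single latent maturity factor m ~ N(0,1) per subject drives every
modality linearly with Gaussian residuals.  The linear-Gaussian form is a
convention chosen for closed-form moments, not a claim about the
real-world law; every population moment used in tests follows from it
analytically.  Defaults (chosen once, a priori, as the simulated study
conditions):

| quantity | default | rationale |
|---|---|---|
| amplitude = 1 + m + e, sd(e) = sqrt(2/3) | signal fraction 0.6 | matches the strength of the observed resting-state prediction |
| RSN loadings | 0.6/0.5 somatomotor, 0.3 others, −0.02 executive | somatomotor-dominant, near-global positive coupling |
| RSN residual sd | 0.15 | network amplitudes read m with little noise (high-SNR MAD estimates) |
| designated-tract MD loading | −0.05, residual sd 0.1545 | per-tract r(MD, m) ≈ −0.31, putting the population 5-tract MD-PC1 amplitude correlation near −0.45 |
| other tract MD loadings | −0.005 | weak global negative trend that stays below the 48-test FWER threshold |
| FA / MK loadings | small positive | maturation increases anisotropy and kurtosis |
| 4D noise | thermal sd 1, AR(1) 0.3, linear drift sd 0.5 | mild autocorrelation; drift exactly captured by the GLM drift term |
| event schedule | 10 × 1 s trials, ≥ 25 s apart | event-related design conventions |
| acquisition | TR 1.3 s; 277 task / 500 rest volumes | desk-scale phantom (24×24×16 at 2 mm) |
| cohort sizes | 18 (event-related) and 215 (resting + diffusion) | the two samples of interest |

A single-factor model cannot simultaneously produce a high MD-PC1 variance
fraction (which needs strong shared tract variance) and a moderate
PC1–amplitude correlation (which needs weak per-tract coupling); defaults
favour matching the correlation, so the simulated PC1 variance fraction is
lower than real neonatal data would show.  Resting runs synthesise network
timeseries with sd = amplitude/0.6745, so the population MAD equals the
requested amplitude (Gaussian MAD/sd = 0.6745) — amplitudes are in the
units the analysis measures.  Motion tables are AR(1) random walks in six
rigid parameters with an optional spike mixture.  Confound and clinical
variables default to zero coupling with m (pure nuisance).

What the generator does **not** emulate: scanner physics, spatial
autocorrelation of noise, motion-induced artefacts coupled to the signal,
non-Gaussian amplitude distributions, or raw diffusion signal (tract
features are generated at the tract-mean level).  Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under the
stated generative model — not that the pipeline is robust to every
artefact of real neonatal data.

## Numerical and degenerate-input conventions

OLS uses `numpy.linalg.lstsq`; designs are checked for full column rank
and rejected otherwise.  Zero-variance voxels: t = 0 with warning (group
map), R² = 0 (GLM).  Constant series: MAD 0, outlier fraction 0, Spearman
of a constant prediction 0.  Li–Ji effective-test eigenvalues are snapped
to integers within 1e-9 before the floor, which is otherwise numerically
unstable at exact-integer eigenvalues.  Inner grid-search ties prefer the
smallest C.  All random number streams are `numpy.random.default_rng`
children of the user seed; liblinear's internal shuffling uses a fixed
state, so identical inputs give identical fits.

## Problem sizes used in tests and the acceptance script

Calibration checks use 300–400 simulated null cohorts with 64–500
permutations; recovery checks use 100–400 seeds; the acceptance pipeline
runs the full 18 + 215 cohort chain at the 24×24×16 phantom with 99
full-pipeline prediction permutations and 1000 screen permutations.  These
sizes give binomial/Monte-Carlo standard errors comfortably inside the
asserted tolerances while keeping the suite desk-scale.
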