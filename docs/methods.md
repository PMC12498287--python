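# Methods

## The model

Structural covariance networks (SCNs) describe how the volume of a seed
structure co-varies, across subjects, with gray matter volume (GMV)
elsewhere in the brain. For a thalamic subfield seed, the per-voxel model is

```
GMV_v = β1·I_CS + β2·I_NC + β3·z(vol)·I_CS + β4·z(vol)·I_NC
        + βa·age_c + βg·gender + Σ_k βs_k·scanner_k + βt·TIV_c + ε_v
```

where `I_CS`/`I_NC` are patient/control indicators, `z(vol)` is the seed
volume standardized over the pooled sample, and the confounders are
centered age, a 0/1 gender code (male = 0), K−1 scanner dummies (reference
level first alphabetically) and centered total intracranial volume. β3 and
β4 are the group-specific covariance slopes; the scientific question is the
contrast **β3 − β4** (patients minus controls), tested voxel-wise with
`t = c'β̂ / √(σ̂² c'(X'X)⁻¹c)` on `n − rank(X)` degrees of freedom.

Pooled (not per-group) z-scoring is the default: per-group standardization
would rescale each group's slope by its own volume dispersion and change
what the contrast measures. A `zscore_mode="per-group"` flag exposes the
alternative. Inference is one-tailed per direction (increased and decreased
covariance tested separately), matching the directional reporting
convention of SPM-style t-contrasts; the opposite direction is obtained by
negating the contrast.

The same model is reused twice: with a target ROI's mean GMV as response
(post-hoc ROI analysis, Bonferroni over all (seed, ROI) pairs tested) and,
with the group indicator as the effect of interest and a subfield volume as
response, for the atrophy comparison (50 tests, Benjamini–Hochberg FDR).

## Cluster-level inference

The study design this package follows corrected cluster extent by
family-wise error. Parametric random-field correction requires smoothness
estimation, which is out of scope here; cluster-extent FWE is instead
controlled nonparametrically by Freedman–Lane permutation:

1. remove the seed-volume columns, fit the reduced model (group means +
   confounds), keep fitted values and residuals;
2. permute residual rows across subjects, add them back to the reduced
   fit, refit the full model;
3. threshold the permuted contrast t-map at the cluster-forming threshold
   (voxel p < 0.001 one-tailed by default) and record the maximum
   suprathreshold cluster extent;
4. after B permutations (default 1000), each observed cluster gets
   `p_fwe = (1 + #{perm max ≥ extent}) / (B + 1)`, so the smallest
   attainable p is 1/(B+1) and p = 0 is impossible.

Because the reduced-model fitted values lie in the column space of the full
design, the permuted-data contrast and residual variance depend only on the
permuted residuals; the implementation batches all permutations into a few
matrix products. The fast path is verified against a literal
residualize–permute–refit loop in the test suite, permutation for
permutation.

Cluster-forming connectivity defaults to 18 (faces + edges), configurable
to 6 or 26. Voxels whose GMV is constant across subjects get a NaN t and
never enter clusters. Voxels lesioned in any patient are removed from the
analysis mask before fitting, so the per-voxel degrees of freedom are
constant across the brain.

## ROI follow-up

Significant-cluster voxels are binarized per seed, unioned across seeds,
and intersected with an integer-labeled atlas. A region is selected when
`intersection / region size` strictly exceeds 0.10 ("exceeds 10%" is read
as a strict inequality; the boundary is unit-tested). Per-subject ROI means
are computed on the lesion-excluded mask only, so patient lesion voxels
never contaminate a mean.

## Behavioral correlations

Partial Spearman: average-rank transform of the measure, the score and the
covariates (age, gender, scanner dummies); covariates plus intercept are
regressed out of the ranked variables and the Pearson correlation of the
residuals is reported with a t-approximation p on n − k − 2 df. Missing
scores are pairwise-deleted per (seed, metric) pair, never imputed, and the
effective n is reported.

The study never defines a per-subject SCN scalar (covariance is a group
property), so the correlate is an explicit operationalization, isolated in
one pluggable function: the subject's cross-term `z(seed volume) × mean GMV
over the selected target ROIs` — the subject-level quantity whose group
covariance the GLM slope measures. A plain ROI-mean variant is available.
BH-FDR runs over the full seed × metric grid, with an uncorrected p < 0.05
exploratory tier whose per-metric and per-seed hit counts are reported.

## The synthetic cohort generator

The generator emulates the output of a voxel-based-morphometry pipeline
plus a thalamic segmentation for a two-group, three-scanner study, with
every planted quantity recorded in a truth object. Defaults are the study
conditions and are not tuned per analysis:

| parameter | default | why |
|---|---|---|
| n_CS / n_NC | 45 / 93 | study sample sizes |
| grid | 16×16×16 @ 1.5 mm | resampled-VBM voxel size on a desk-scale grid; the full pipeline runs in ~1 s |
| noise smoothing | 6 mm FWHM | VBM smoothing kernel |
| baseline GMV | 10 (arb. units) | keeps GMV effectively positive at noise SD 1 |
| noise SD | 1.0 | one SD per voxel after smoothing; with the default slopes this is contrast SNR 1 |
| planted slopes (CS/NC) | 2 / 1 | a detectable but not trivial covariance difference; `with_snr()` rescales noise to any SNR |
| effect blob | 5³ voxels (7.5 mm cube) | comparable to the smoothing kernel and to reported cortical cluster sizes; a 3³ blob would be smaller than typical null maximum cluster extents on this grid |
| subfield volume CV | 0.20 | realistic inter-subject variability for automated thalamic subfield volumetry (~15–25%) |
| ipsilesional atrophy | 20% (multiplicative) | proportional volume loss in patients, effect size d = 1 against the 20% CV — strong enough that all 25 subfields are detectable at n = 138, as in the study |
| inter-subfield correlation | 0.30 | shared subject-level size factor |
| scanner offsets | (0, +0.15, −0.1) | additive site effects |
| lesions | spheres r ≈ 1.2–2.2 voxels, right internal-capsule territory | focal capsular lesions (~25–110 mm³); they zero the patient's GMV, and exclusion is the analysis mask's job |

The noise field is white Gaussian noise convolved with a Gaussian kernel
(wrap-around boundary, so it is exactly stationary) and rescaled by the
kernel's L2 norm to unit marginal variance. Smoothing is applied to the
noise only and effects are block-shaped, so planted slopes are exactly
recoverable on noise-free data — the basis of the exact-recovery tests.
Confound effects enter through the same centered covariates the design
matrix uses, hence lie in the model's column space.

Clinical scores are group-baseline + optional linear terms in chosen
subfield volumes + Gaussian noise, with accuracies clipped to [0, 1] and
reaction times kept positive. Default coefficients are weak, mirroring a
cohort with good functional recovery where no correlation survives FDR.

One generator interaction worth knowing: a group covariance equals
slope × within-group z-variance, and multiplicative atrophy shrinks the
patient group's volume dispersion (factor 0.8). The raw covariance gap is
therefore much smaller than the slope gap, and the Monte-Carlo rate at
which *sample covariances* order correctly at SNR 0.5 is ≈ 0.80, not ≈ 1.
The GLM estimates slopes, not covariances, so pipeline power is unaffected.

### What the generator does not emulate

No anatomy (no template, no tissue classes), no registration error, no
scanner-specific noise spectra beyond an additive offset, no non-Gaussian
VBM noise, no spatial structure in the confound effects, and lesions with
sharp spherical boundaries. Passing tests therefore demonstrate that the
*statistical machinery* is correct and calibrated under the model's own
assumptions — not that the pipeline is robust to registration failure or
segmentation error in real MRI.

## Numerical and calibration choices

- Affine equality tolerance 1e-4 mm (header jitter below physical meaning).
- Mass-univariate OLS via `lstsq`; agreement with per-voxel reference OLS
  asserted to 1e-8 on random voxels.
- Degenerate inputs: constant seed volumes, single-group cohorts,
  rank-deficient designs (named-column error), constant-GMV voxels (NaN t),
  empty lesion masks (rejected unless explicitly allowed), ROIs emptied by
  the exclusion mask (warn + drop).
- Voxel-level type-I calibration: the suprathreshold fraction at p < 0.001
  has expectation exactly 0.001 per voxel, but smoothing correlates voxels,
  so a pooled-count binomial bound is only valid for unsmoothed noise; the
  calibration test checks the binomial bound on independent-noise cohorts
  and an across-cohort 99% t-interval under the study's smoothing.
- Cluster-FWE calibration: proportion of null cohorts with any
  FWE-significant cluster compared against the 99th percentile of
  Binomial(n, 0.05).
- Problem sizes in the shipped tests and acceptance script (50–100 null
  cohorts, B = 500, 20–50 recovery replicates on the 16³ grid) were chosen
  so the whole battery runs on a laptop in minutes; all sizes are arguments
  and scale up unchanged.

## Known limitations

- Permutation exchangeability assumes i.i.d. model errors across subjects;
  heteroscedasticity by group is not modeled (the study's SPM analysis
  assumes the same).
- The per-subject SCN correlate for behavioral screening is an
  interpretive choice; alternatives plug into `scn_measure`.
- With the pooled 50-test BH family and 25 strong true atrophy effects,
  the step-up cutoff for the remaining null tests rises to ≈ q·26/50, so
  occasional contralesional false discoveries are expected by design of
  BH; the per-hemisphere family option keeps the null hemisphere clean at
  the 5% level.
- The one-sample KS screen uses estimated mean/SD without a Lilliefors
  correction, making it conservative for near-normal data.
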