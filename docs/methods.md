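# Methods

## Pipeline overview

`meglat` estimates the laterality of the epileptic focus in unilateral mesial
temporal lobe epilepsy (MTLE) from resting-state MEG band power. The stages,
in order: sensor preprocessing (epoching, amplitude-based artifact rejection,
power-line notch, band filtering), source-power estimation on a toy geometry
(coherence-prior minimum-norm inverse, Morlet band power, trial averaging,
lobar summarization), laterality indices with control-baseline correction,
group statistics (factorial ANOVA with a pooled bootstrap, per-cell bootstrap
tests with FDR, mass-univariate ANCOVA with permutation FWE), and a
linear-SVM leave-one-out classifier. A synthetic-data module generates every
input so the whole pipeline is testable without patient data.

## Preprocessing

Recordings (channels × samples, fT) are cut into non-overlapping 10-s epochs
(trailing remainder dropped); an epoch is discarded iff any channel exceeds
6,000 fT in absolute value at any sample (the rule is interpreted as absolute
amplitude, not peak-to-peak). The power-line component (60 Hz for the patient
site, 50 Hz for the control site) is removed with a 2-Hz-wide order-4
Butterworth band-stop; band-limited signals use order-4 Butterworth
bandpasses. All filters run forward–backward (`sosfiltfilt`), hence
zero-phase with doubled attenuation; the notch attenuates the utility tone by
well over 20 dB while changing tones 3 Hz away by under 1 dB. The delta band's
lower edge is 0.3 Hz — the hardware high-pass of the acquisition chain —
because a 0-Hz bandpass edge is unrealizable. Gaps between printed band edges
(e.g. 3–4 Hz) fall in the filters' transition regions; no sample-level
reassignment is attempted.

## Toy geometry and source power

Sources sit in eight clusters (frontal, temporal, parietal, occipital × left,
right) jittered around fixed centroids on a unit hemisphere; hemisphere
membership is the sign of the lateral coordinate (x < 0 ⇒ left) and each
source is kept at least 0.05 R off the midline. Sensors form a quasi-uniform
(Fibonacci) shell at 1.3 R. The gain is an isotropic inverse-square kernel
g = 1/(0.05 + d²) — a deliberate simplification that preserves the geometry
of the inverse problem without a biophysical forward model.

The inverse is linear minimum-norm with a spatial-coherence source prior,

    J = R Gᵀ (G R Gᵀ + λI)⁻¹ B,   R_ij = exp(−‖s_i − s_j‖² / 2σ²),

with σ = 0.2 × geometry radius and λ = 0.1 × mean diagonal of G R Gᵀ by
default. This keeps the defining idea of coherence-prior estimators (akin to
sLORETA) while remaining deterministic and desk-scale; no hyperparameter
optimization is performed. Band power per source is the squared-magnitude
Morlet transform (7 cycles) averaged over a 1-Hz in-band frequency grid and
over time, excluding half the wavelet support at each edge; trials (retained
epochs) are averaged arithmetically. Because the inverse is linear and
band-independent, the pipeline computes the inverse operator once and applies
it to each band-filtered epoch — identical to inverting each band separately.
Region × hemisphere power is the mean over member sources.

On well-separated grids (one source per cluster) the noiseless single-source
localization is exact; with several sources per cluster the coherence prior
can prefer an immediate neighbor, but the peak stays inside the true
region × hemisphere cell, which is the resolution the laterality analysis
uses.

## Laterality indices

LI = (P_L − P_R)/(P_L + P_R) per band × region, strictly inside (−1, 1) for
positive powers; +1 means fully left-dominant. Powers below 1e−12 raise an
error rather than clamp, since the index is undefined at zero total power.
Healthy brains lateralize, so patient LIs are baseline-corrected by
subtracting the control group's arithmetic mean LI per band × region
(corrected values lie in (−2, 2)). The 28-feature vector is ordered
band-major (delta…HFO × frontal, temporal, parietal, occipital); the ordering
is fixed so feature matrices are reproducible across runs.

## Group statistics

**Factorial ANOVA.** Per band, baseline-corrected LIs enter a 2 (group) × 4
(region) ANOVA with Type III sums of squares and sum-to-zero coding; each
subject's four region values are treated as independent cells (a
repeated-measures variant is out of scope). Degenerate inputs (zero residual
variance) report F = 0 with a flag.

**Pooled bootstrap.** All n observations are resampled with replacement
ignoring group and region, redealt into the original design cells, and the F
statistics recomputed 20,000 times; the smaller of the two inclusive tail
proportions around the observed F is the reported significance level. Because
the resampling preserves the cell structure, the projection (hat) matrices
are constant and each resampled F reduces to quadratic forms — the 20,000
resamples cost three matrix products.

**Bootstrap mean tests.** One-sample tests against zero (patient group vs the
control baseline) and two-sample tests (left vs right patients) resample each
group with replacement and report the smaller strict tail proportion of the
resampled mean (or mean difference) around zero. The smaller-tail rule is
implemented literally — the minimum one-tailed proportion, not doubled —
because that is the reporting convention of the results tables this package
mirrors; it is a one-sided level, and under the null it rejects at roughly
twice the threshold. A `two_sided=True` option doubles the value (capped at
1) for conventionally calibrated decisions, and the calibration tests use it.
Both tests sort their inputs before resampling, making the p value exactly
invariant to observation order. Ties (resamples exactly equal to the
reference) follow each rule's stated comparison: inclusive for the F
bootstrap, strict against zero for the mean tests; on continuous data the
distinction has probability zero.

Calibration, measured by simulation: in the asymptotic regime (n ≈ 80 per
group) the two-sided rates sit within 3 binomial SEs of nominal at α = 0.01
and 0.05 (1,000 replicate datasets, 1,000 resamples each). At the study's own
group sizes (16/19) the percentile bootstrap is mildly anticonservative at
α = 0.01 (≈ 0.02), a known small-sample property of percentile methods (the
normal-vs-t quantile gap), so the calibration suite uses the larger sizes and
the cohort-level null check uses α = 0.05.

**Multiple testing.** Benjamini–Hochberg step-up adjustment is applied
separately per test family (one-sample left, one-sample right, two-sample)
across the 28 band × region p values; significance means adjusted p ≤ 0.05.

**Mass-univariate ANCOVA.** Per source, a one-way group F (LtMTLE, RtMTLE,
controls) after regressing out age; the omnibus test and the three pairwise
contrasts are each corrected family-wise by the max-statistic distribution
over permutations of the group labels (default 1,000; p = (1 + #(max F* ≥
F))/(n_perm + 1)). This replaces random-field-theory corrections, which
require a smooth lattice geometry this toy model does not have.

## Classification

The 28 LIs are standardized over the whole dataset (population SD), the
printed protocol; note this leaks scaling information across
cross-validation folds, and a `per_fold` option fits the scaler inside each
training fold instead. The classifier is a linear-kernel SVM with fixed
hyperparameters (C = 1, no class weighting, no tuning loop), evaluated by
leave-one-out cross-validation in two scenarios (left patients vs controls:
118 iterations; right patients vs controls: 121). Posterior probabilities
come from a Platt sigmoid — two-parameter logistic MLE with Platt's smoothed
targets — fitted on the training fold's decision values, so the held-out
sample never influences its own calibration; the smoothed targets keep the
fit finite on separable folds. Raw (uncorrected) LIs are the default
predictors; standardization over the dataset makes baseline correction a
per-feature shift that the scaler absorbs in the control-heavy scenarios.
Confusion metrics are accuracy (TP+TN)/(TP+FP+TN+FN), sensitivity
TP/(TP+FN), specificity TN/(FP+TN); the ROC sweeps the unique posterior
values (tied scores share one threshold step) and the AUC is the trapezoidal
integral, which equals the Mann–Whitney U statistic divided by n₁n₀.

Concordance with the conventional dipole-fit (ECD) reading cross-tabulates,
over the 35 packaged patients, whether each method lateralized (ECD ∈ {L, R}
vs Bilateral/No spike; SVM ∈ {L, R} vs control-like) and whether two
unilateral calls agree on the side.

## Synthetic data

The generator emulates the study conditions: 102 controls, 16 left-focus and
19 right-focus patients; 7 bands × 4 regions × 2 hemispheres of strictly
positive power per subject; ages uniform on 8–75 years (covering the printed
ranges; sex is not modeled because no analysis uses it). Log power is

    log P = μ_f + s_i ± artanh(b[f,r]) + δ[f,r]·[h = ipsi] + ε,

with band levels μ_f on a 1/f-like profile with an alpha bump, a shared
subject scaling s_i ~ N(0, 0.3²) (cancels in every LI), a control
lateralization bias b (defaults: +0.03/+0.05/−0.04/+0.02 for frontal/
temporal/parietal/occipital — healthy hemispheres are not symmetric), an
ipsilateral elevation δ ≥ 0 applied to the focus-side hemisphere of patient
groups, and i.i.d. cell noise ε ~ N(0, log(1 + cv²)) so that `noise_cv` is
the coefficient of variation of power. In the noise-free limit the control
LI equals b exactly and the patient log-power ratio shifts by δ. With noise,
E[LI] = E[tanh((2·artanh b + δ + ε_L − ε_R)/2)]; the tests evaluate this
expectation by Gauss–Hermite quadrature rather than the noise-free
tanh(δ/2), which is biased at O(σ²).

Defaults chosen once: `noise_cv = 0.3` (the within-group LI dispersion is not
characterized by any published table, so this is a realistic free choice, not
an estimate); δ strongest in temporal/parietal theta (0.6) and tapering with
band and region, matching the reported topography of oscillatory changes.
The sensor simulator places sinusoidal sources on the toy geometry, projects
them through the same gain kernel, and adds white sensor noise, a common-mode
utility-frequency tone, and — on request — 8,000 fT excursions in chosen
epochs so the rejection rule has known ground truth.

What the generator does not emulate: 1/f-continuous spectra, spatial noise
correlations, realistic head geometry or gain physics, non-log-normal power
distributions, and any age or sex dependence of power (an optional age slope
exists only for exercising the nuisance covariate). Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under a controlled model, not clinical performance on real MEG.

## Problem sizes and numerical choices

Test and acceptance runs use reduced problem sizes chosen to exercise each
property at adequate statistical resolution: 500 replicate cohorts for null
fidelity, 1,000 replicates × 1,000 resamples for type-I calibration, 150–200
null simulations at 199 permutations for family-wise error, 24–32 toy
sources, and 20-s recordings at 250–500 Hz for end-to-end checks. Bootstrap
and permutation p values are reproducible given a seed; per-test RNG streams
are spawned from one root seed. Zero-variance features, empty geometry cells,
rank-deficient designs, all-rejected epochs, and non-positive powers raise
errors rather than producing silent results.

## Known limitations

The toy inverse is not a clinical source estimator; regions are coordinate
clusters, not atlas masks. The factorial ANOVA ignores the within-subject
correlation of region values. The literal smaller-tail bootstrap rule is
anticonservative if read as a two-sided level (see above). Whole-dataset
standardization leaks across folds; the per-fold option is provided but is
not the default because the default mirrors the published protocol. The SVM
uses fixed hyperparameters by design; no feature selection or model
comparison is attempted.
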