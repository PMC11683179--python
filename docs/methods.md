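# Methods

This note documents the models, numerical choices and limitations of the
`aidhs` pipeline, stage by stage, and what the synthetic cohorts do and do
not establish.

## Inputs and quality control

The pipeline consumes the outputs of an upstream hippocampal surface
segmentation: per-vertex maps (thickness mm, gyrification index, mean
curvature mm⁻¹, intrinsic curvature mm⁻²) on a fixed-topology mid-thickness
mesh with an anterior–posterior (AP) coordinate in [0, 1], per-hemisphere
volumes (mm³), per-hemisphere Dice QC scores, and a demographics CSV
(subjects must be older than 3 years; HS patients carry a left/right/
bilateral label, everyone else `none`). Metrics are accepted as GIFTI
(`.shape.gii`, float32 by format) or wide CSV tables (full float64
round-trip). Subjects whose worse-hemisphere Dice falls below 0.7 are
auto-flagged for exclusion; the threshold is strict "below" (exactly 0.7 is
retained), and a `passed` override column replaces interactive visual review
in this headless setting.

## Vertex preprocessing

1. **Outlier replacement** — vertices outside mean ± 5 SD of the map are
   replaced by the mean of their non-flagged 1-ring neighbors (breadth-first
   search finds the nearest non-outliers when an entire ring is flagged);
   mean/SD are recomputed each sweep until a fixed point or 10 sweeps. A map
   whose every vertex is flagged is rejected as degenerate. Note the gate
   has an intrinsic resolution floor: a lone spike among *n* vertices can
   reach at most ≈ √n SDs of the map's own distribution, so tiny meshes
   cannot trigger a 5-SD gate at all.
2. **Smoothing** — a single linear operator with weights
   exp(−d²/2σ²) on graph geodesic distances (Dijkstra along mesh edges),
   σ = FWHM/2.3548, truncated at 4σ and row-normalized. We chose the direct
   geodesic kernel over iterated 1-ring averaging because at the default
   1 mm FWHM σ (≈0.42 mm) is below typical vertex spacing, where a composed
   1-ring kernel deviates >10% from the target Gaussian purely through
   truncated mass; the direct operator is non-negative, preserves constants
   exactly, matches a dense-kernel oracle within 10% out to 2σ, and is
   linear and order-independent across features. FWHM 0 is the identity.
3. **Trimmed averaging** — the per-hippocampus scalar is the mean over
   vertices whose AP coordinate lies within the [q₀.₀₁, q₀.₉₉] quantile band
   (quantile-, not rank-based, hence mesh-resolution independent; applied
   per hemisphere). Volume bypasses all three steps.

## Harmonization (ComBat)

Parametric empirical-Bayes location/scale adjustment with sites as batches,
implemented in-package (no maintained Python implementation ships with the
standard stack) and cross-checked in the test suite against Bioconductor
`sva::ComBat`, to which it agrees at machine precision. The 10 columns are
the 5 features × 2 hemispheres — hemispheres as separate columns preserves
within-subject pairing. Covariates re-added after adjustment: age (linear),
sex (binary), disease status (two dummies: patient, disease-control;
healthy-control reference). Priors are the standard normal (locations) and
inverse-gamma (scales) with iterative moment-matched posterior estimates
(tolerance 1e-4). A minimum of 20 subjects per site is enforced; fitting a
single site is an error that points to the supported no-op mode
(`enabled=False`), since the pipeline is designed to run with and without
harmonization. Applying a model to a site unseen at fit time either errors
or, in the documented fallback used for held-out sites during
cross-validation, passes features through unadjusted with a warning — the
downstream asymmetry index cancels multiplicative site effects exactly and
most of additive ones, which is what makes the unharmonized regime viable.

What "removing the site effect" can promise: the *pooled* between-site mean
gap (averaged over feature columns) is driven to a fraction of a percent of
an injected 1-SD shift; any single column retains the sampling noise of two
site means (≈ sd·√(2/n)), which no mean-matching method can undercut.

## Asymmetry and normalization

AI = 2(lh − rh)/(lh + rh): antisymmetric under hemisphere swap, bounded in
(−2, 2) for positive features, zero at symmetry. A single left-referenced
vector per subject suffices (the right hippocampus is its negation).
Normalized asymmetries are z-scores against the mean and SD (ddof = 1) of
the *healthy* controls of the training sample only — disease controls are
excluded, and in cross-validation the statistics are refit per fold after
fold harmonization so no held-out-site information leaks into them. The
reference controls self-normalize to exactly mean 0 / SD 1.

## Normative growth charts

Per feature and sex, a Gaussian location GAM: penalized cubic B-spline
smooth of age (basis dimension 5 — small control cohorts do not support
more), penalty weight selected by generalized cross-validation on a fixed
log grid (10⁻³…10⁸, deterministic given data), constant residual SD per
feature × sex. Both hemispheres of each control enter as observations
(hemisphere ignored; the left–right offsets are small relative to residual
SD, slightly widening the band). The p-th centile is μ̂(age) + z_p·σ̂, so
centile curves are ordered by construction and the 5th–95th band has width
2·1.6449·σ̂. Percentile scores are 100·Φ((x − μ̂)/σ̂), clipped to
(0.1, 99.9) only for display. Ages outside the training support evaluate at
the nearest supported age with a warning. A sex stratum under 10
observations is an error; under 30 controls a warning. ICV adjustment is
deliberately not included. The Gaussian location model (rather than
quantile regression or a heteroscedastic GAMLSS) is the minimal model that
supports closed-form centiles and calibration testing; skewed or
heteroscedastic features would miscalibrate its tails.

## Classifier, decisions, cross-validation

Multinomial logistic regression on the 5 normalized asymmetries: lbfgs,
balanced class weights, tolerance 1e-6, max 1000 iterations, weak L2
(C = 1.0; disable with C = ∞) to stabilize small folds. Scores are ordered
[S_LHS, S_RHS, S_noHS]. Decisions: detection is noHS iff S_noHS ≥
max(S_LHS, S_RHS) (ties conservatively noHS); lateralization is left iff
S_LHS ≥ S_RHS (exact ties logged and called left); lateralization is defined
for every subject regardless of detection. Leave-one-site-out: one fold per
site; each fold owns its harmonizer, control statistics, classifier and
abnormality thresholds, all fit on its training sites only — deleting the
held-out rows from memory reproduces bit-identical fold models. The
deployment ensemble averages fold probability vectors and renormalizes
(the minimal convention; identical folds reduce to a single model).
Bilateral-HS subjects never enter training; they are predicted and reported
only. Abnormality thresholds per feature and side are the probability-0.5
boundary (−intercept/slope) of an unregularized univariate logistic fit of
that side's patients against all controls; absent separation (or absent
patients of a side) the threshold is undefined and flagged, never invented.
A volume-only baseline (volume asymmetry through the identical protocol)
supports comparisons; with signal confined to volume it matches the full
model, and with signal in curvature only it clearly trails it.

## Evaluation statistics

Detection sensitivity = unilateral patients decided HS; lateralization
sensitivity = correct side among unilateral patients (bilateral excluded —
no single correct side exists); specificity = controls decided noHS.
Stratified breakdowns (adults ≥ 18 vs children, sex, MRI status, histology,
outcome, resolution) come with a multivariable logistic regression of
per-subject correctness; under separation or constant outcomes coefficients
are reported as non-converged rather than fabricated. Group contrasts of
ipsilateral normalized asymmetries (controls contribute one seeded-random
hemisphere each; right-referenced values are sign-flipped before z-scoring)
use Welch's t when both samples pass Shapiro–Wilk at p ≥ 0.05, otherwise
Mann–Whitney, Holm-corrected across all feature × pair tests. The
sex-by-group association is a Pearson chi-square without continuity
correction.

## Synthetic cohorts

Per subject, hemisphere and feature: a saturating age trajectory
a + b(1 − e^(−age/τ)) plus sex and hemisphere offsets, a between-subject
effect shared across hemispheres, an independent per-hemisphere residual, an
additive site shift (in units of the between-subject SD) and a
multiplicative site scale. The ipsilateral hemisphere of a patient is
multiplied by a per-feature effect factor (< 1 for volume/thickness/
gyrification, > 1 for the curvatures), jittered across patients. Vertex
maps add a zero-mean AP profile and spatially smoothed noise around the
scalar target, with a configurable rate of injected outlier spikes; volumes
are scalar-only. Dice scores are high-valued with optional failure
injection. Defaults: 4 sites × (50 left-HS + 50 right-HS + 50 healthy + 50
disease controls), ages uniform on 7–60 years, volume ≈ 3 mm³·10³ scale,
thickness ≈ 1.6 mm, gyrification ≈ 3 — plausible magnitudes, documented as
arbitrary. The effect multipliers (0.70/0.89/0.82 down, 1.16/1.27 up) were
calibrated once against the normative model's realized control residual SD
so the simulated ipsilateral deviation profile matches the intended one
(~90% of patients below the 5th volume centile, smaller fractions for the
other features); they are generator conditions, not fitted quantities. The
default surface is a 32 × 16 folded half-tube grid (512 vertices) — small
enough that the full 800-subject pipeline runs in seconds, large enough for
non-trivial geodesics.

What the generator does *not* emulate: realistic hippocampal geometry,
spatially structured (subfield-specific) lesion patterns, non-Gaussian or
age-dependent feature variance, site-by-age interactions, segmentation
failure modes that corrupt features rather than Dice. Passing tests
therefore demonstrate correctness of the pipeline's statistics and
protocols under the stated generative model — not clinical performance,
which can only be established on real cohorts. The synthetic cohorts are
deliberately well-separated; near-perfect LOSO scores on them are a
parameter-recovery check, not a performance claim.

## Problem sizes

Test and script problem sizes were chosen as the smallest that make each
statistical check well-powered: the LOSO recovery and null experiments use
the default 800-subject cohort; harmonization recovery two sites of 200;
normative calibration 500 training + 1000 held-out controls; the decision
oracle 10⁴ triplets. The whole suite runs in well under a minute.

## Known limitations

Bilateral-HS detection and HS subtyping are out of scope (reports still
surface bilateral abnormality patterns). The normative model is
homoscedastic Gaussian. Held-out sites are passed through unharmonized
rather than harmonized by transfer. The GIFTI dialect stores float32.
Whether the upstream study pooled hemispheres in its charts, averaged
probabilities in its ensemble, or gated its normality tests at 0.05 is not
derivable from public sources; the choices above are this package's own and
are stated where they matter.
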