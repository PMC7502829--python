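# Methods

`lesionload` implements an individual-level lesion-load analysis of
skeletonized fractional-anisotropy (FA) maps after mild traumatic brain
injury, and the prognostic models built on top of it. The pipeline
starts from already-skeletonized FA in a common space (TBSS-style
output); registration, tensor fitting and skeletonization are out of
scope.

## Normative EZ deviation maps

A control cohort is split into two covariate-balanced halves — a
*reference group* that defines healthy norms and *normal controls* held
out to calibrate thresholds. The split uses greedy nearest-neighbour
pairing in standardized (age, sex, education) space with a random,
seeded assignment within each pair.

Per skeleton voxel, FA is regressed on age, sex (0/1) and education
(years) in the reference group by ordinary least squares. Covariates
are stored uncentred and centred at reference means inside the model, so
"a subject at the reference mean" is exactly the identity case. A voxel
is *covariate-significant* when the regression's omnibus F-test has
p < .05, deliberately uncorrected for multiplicity: the adjustment mask
is a modelling choice, not an inference.

A subject's adjusted FA subtracts (covariate deviation from reference
means) · slopes at significant voxels only, and the deviation map is

    EZ(v) = (FA_adj(v) − μ(v)) / σ(v),

flagged two-tailed at the conventional |EZ| > 1.96 (strict inequality;
the boundary is not flagged).

**Bootstrap aggregation.** To absorb reference sample-to-sample
variation, μ and σ aggregate B bootstrap replicates (default B = 1000;
tests and the shipped pipeline use 40–200, which the stabilization test
shows is ample at these grid sizes). Each replicate refits the
covariate slopes on a resample drawn with replacement, then adjusts the
*full* set of n distinct reference subjects under the frozen full-fit
significance mask, accumulating per-voxel means and variances.
Computing replicate variances over the resampled rows themselves would
shrink them through duplicate subjects; computing them over the distinct
subjects with replicate-refitted slopes instead propagates exactly the
coefficient sampling variation the bootstrap is meant to capture.

**Predictive σ.** A z-score built from a small-sample σ̂ over-flags:
for a held-out subject, (x − x̄)/(s·√(1+1/n)) follows a t distribution,
not a normal. σ is therefore a *predictive* SD:

* regression degrees of freedom restored at adjusted voxels
  (variance × (n−1)/(n−1−p), p = 3 slopes);
* inflation by √(1 + (1+p_v)/n) for the sampling error of the mean and
  of the adjustment (p_v = 3 at adjusted voxels, else 0);
* scaling by t_{ν,.975}/z_{.975} (ν = n−1−p_v) so the fixed normal
  threshold 1.96 attains its nominal 5% two-tailed rate.

With these corrections, held-out null controls show a 5.0–5.5% flag
rate and per-voxel EZ mean ≈ 0, SD ≈ 1.0 at reference sizes 20–30,
with or without true covariate effects. σ = 0 anywhere is treated as a
hard error (degenerate input), not floored.

## Clusters, GRF extent correction, lesion-load features

Suprathreshold voxels (EZ > u for raised FA, EZ < −u for lowered FA,
handled independently so a tract can contribute both directions) are
masked to atlas tracts; connected components are computed **within each
tract** under 26-connectivity (skeletons are thin; face-only adjacency
fragments genuinely contiguous tracts), and components smaller than the
extent threshold k are discarded.

k controls the family-wise rate of suprathreshold clusters at α (default
.05, one-sided per direction) using the classical smooth-Gaussian-field
approximation: expected cluster count from the Euler-characteristic
density, expected extent from the suprathreshold volume, and a
stretched-exponential extent tail. Smoothness is estimated from the
variance of lag-one spatial differences of standardized residual maps
(adjacent on-skeleton pairs only), inverted through the Gaussian
autocorrelation and clipped below at one voxel size. Because a skeleton
is quasi-2D the analytic k is approximate; a Monte-Carlo mode
(`--mode mc`, toroidal smooth null fields) is provided, and the analytic
threshold sits within ~15% (above) of the Monte-Carlo 95th percentile at
the tested conditions — conservative in the right direction.

The voxel/extent threshold pair can also be chosen by a ROC sweep
maximizing patient-vs-control separation of total lesion load, with ties
broken toward stricter thresholds; the shipped default when the sweep is
skipped is u = 1.96, α = .05.

**Group catalogue.** Feature cutting needs one fixed cluster set shared
by every subject, including external-cohort subjects scored later. Per direction, a voxel enters the group mask when
abnormal in at least `frequency_fraction` (default 0.25) of patients;
clusters cut from that mask form the catalogue, and each subject's
feature is their mean covariate-adjusted FA over each catalogue cluster
(adjusted, for consistency with the EZ pipeline). An empty catalogue is
a warning, not an error: the pipeline continues on cytokine features.

## Prognostic models

Classification of recovered (+1) vs not-recovered (−1) patients uses a
linear soft-margin SVM (C = 1) with recursive feature elimination:
standardize, fit, drop the feature with the smallest |weight|, repeat;
the surviving subset with the best cross-validated accuracy wins, ties
toward fewer features. Final weights are max-normalized, so the top
feature's weight is 1 by construction. Per-step accuracy uses
stratified 5-fold CV on training data by default (`inner_cv="loo"` gives
the exhaustive variant; 5-fold keeps nested validation and per-
permutation refits tractable at these cohort sizes).

Class weights are balanced in every SVM fit. The not-recovered class is
the clinically positive minority (~33%), and an unweighted hinge loss
degenerates to majority-class predictions whenever signal is weak — which
both destroys sensitivity on the class that matters and pins null-data
accuracy at the majority rate (measured 66.6% on shuffled labels)
instead of chance (53% with balancing).

Validation:

* **LOOCV** with standardization refit per fold; sensitivity is recall
  of the −1 class, specificity of the +1 class, and every report records
  this convention. The leakage-free mode reruns RFE inside each fold.
* **Repeated subsampling** of n = 1..8 test subjects (percentile CIs of
  the accuracy distribution); an exhaustive n = 1 mode reproduces LOOCV
  exactly.
* **Permutation test**: class-count-preserving label permutations,
  p = (1 + #{perm ≥ observed})/(1 + n_perm) (add-one smoothing). The
  full mode refits RFE per permutation; the fast mode (fixed subset) is
  labelled as such in reports.
* **SVR** (linear, ε = 0.1 in SD units of the fold-standardized score)
  predicts continuous scores with the classification-selected subset —
  no re-selection for the second score — and reports Spearman ρ with a
  subject-bootstrap CI.
* **Domain combination** concatenates imaging and cytokine features,
  each domain z-scored separately.
* **External validation** applies the frozen model (scaler, subset,
  weights) once to a replicate cohort whose features were cut with the
  original catalogue and normative model; identical inputs give
  bit-identical reports.
* **Importance filtering** keeps clusters in the top 25% of normalized
  weights (floor(0.25 · n_fibers), so 27 fibers keep 6) and then
  requires not-recovered vs recovered *and* not-recovered vs controls
  differences at the Bonferroni level 0.05/m.
* **Group statistics**: Shapiro–Wilk gates Student's t vs Mann–Whitney;
  Cohen's d from the pooled SD; percentile-bootstrap CI of the mean
  difference.

## Synthetic cohort generator

No clinical data ship with the package; the generator reproduces the
statistical structure the analysis assumes, with defaults chosen once to
mirror the study design (original sample: 60 patients / 40 controls;
replicate: same conditions, fresh draw).

* **Grid and skeleton**: 48×48×24 voxels at 2 mm, partitioned into 12
  rectangular tract blocks; the skeleton is a thin slab through each
  block (~10–12% of voxels), contiguous per tract under 26-connectivity
  the way a real tract skeleton is. Deterministic and seed-free, so
  original and replicate cohorts share one common space.
* **Control FA**: per-tract baseline in [0.40, 0.55] plus linear
  covariate effects (age −0.001/yr, sex +0.01, education +0.0005/yr —
  FA-scale effects of the size reported for healthy aging) plus
  unit-variance-exact smooth Gaussian noise (white noise convolved on a
  torus at FWHM 4 mm, SD 0.03 FA units between subjects). Ages 18–59
  and education 5–16 integer years, inside the norms-table bands.
* **Lesions**: contiguous blobs grown deterministically (breadth-first,
  nearest-centroid-first) inside named tracts; defaults inject four
  lesions (three low-FA, one high-FA) of 120 voxels at 4.0 reference-SD
  effect with prevalence 1.0 among designated non-recovered patients
  (33% of patients). Recovered patients carry the same sites at 0.3×
  effect and 0.5 prevalence: injury is graded, not all-or-none. The
  4-SD / 120-voxel default keeps the frequency-pooled group mask above
  the 0.25 pooling threshold at 33% outcome prevalence and the extent
  above twice the GRF threshold (k ≈ 45–55 on this grid).
* **Cytokines** (pg/mL): control levels near published healthy means
  (IL-1β 2.2, IL-6 0.9, CCL2 212); all patients shifted by (+0.4, +0.4,
  +47) and non-recovered patients by a further (+0.3, +0.15, +25) — an
  acute inflammatory elevation carrying deliberately weaker outcome
  signal than imaging, so the cytokine-only model performs modestly.
* **Outcomes**: follow-up TMT-A (s) = 24 + 0.02 · burden + N(0, 3) and
  follow-up BDS = 5 − 0.0012 · burden + N(0, 0.8), where burden sums
  effect × extent × jitter over a subject's lesions (jitter U(0.8, 1.2)
  gives within-group severity gradients); baselines are worse versions
  of follow-up. The BDS link is intentionally weaker and noisier (span
  counts are coarse), so its predicted-vs-actual correlation runs below
  the IPS one. Recovery labels derive from follow-up TMT-A against a
  banded (age × education) cut-off table, inclusive at the cut-off.
  Published norms tables are licensed and not redistributable, so the
  shipped table (`data/tmt_a_norms_synthetic.csv`) is a synthetic
  stand-in on a realistic seconds scale.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: registration and skeleton-projection error,
non-Gaussian and spatially non-stationary noise, curved tract geometry,
partial-volume effects, lesion heterogeneity across subjects' anatomy
(lesion sites coincide across carriers by construction), practice
effects on repeat testing, and covariate distributions beyond uniform
age/education. Group-level performance numbers on these cohorts
(accuracies in the high 90s) characterize the pipeline under its own
assumptions, not expected clinical performance.

## Problem sizes and numerical choices

The test suite and acceptance script run on the default 48×48×24 grid
(~7k skeleton voxels; ~10k for calibration checks), bootstrap B = 40–100,
20-seed sweeps, 500 permutations (fast mode) and a 5,000-field
Monte-Carlo null — sizes chosen so a full run completes in minutes on
one CPU while keeping every statistical check at the study's own cohort
dimensions. Degenerate inputs fail loudly by design: σ = 0 voxels,
rank-deficient covariate designs (named covariate), subjects outside all
norm bands (listed), lesions that do not fit their tract, orphan atlas
labels, shape/affine mismatches (offending file named). One global seed
fans out to per-stage seeds by fixed offsets, and every report embeds
the configuration hash and stage seeds.

## Known limitations

* GRF theory on a quasi-2D skeleton is approximate; the analytic extent
  threshold runs ~15% conservative against the Monte-Carlo null at the
  tested smoothness. Use `--mode mc` where exactness matters.
* The frequency-pooling rule (0.25) that fixes the group catalogue is a
  documented choice; the underlying group-level pooling is not uniquely
  determined by the method description the package follows.
* Single-run LOOCV accuracies disperse widely (SD ≈ 10 points at n = 60)
  because fold predictions share training data; point accuracies should
  be read together with the subsampling CIs.
* Covariate-significance masking is uncorrected by design; the mask is
  unstable at small reference sizes.
* The permutation test's fast mode conditions on the selected subset and
  is anti-conservative relative to the full mode; reports label which
  mode produced p.
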