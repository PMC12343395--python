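# Methods

vicikit implements a complete case-control neuroimaging analysis chain —
voxel-based-morphometry (VBM) group statistics, classifier benchmarking on
suprathreshold voxels, Shapley-value attribution, the volumetric integrated
classification index (VICI), and imaging-transcriptomic gene association —
together with a seeded synthetic-cohort generator that provides the inputs
every stage assumes. This note records the models, the defaults and why
they are what they are, the numerical choices, and what the synthetic
setting does and does not demonstrate.

## The synthetic cohort

The generator emulates the statistical structure of a preprocessed,
modulated, smoothed gray-matter-volume (GMV) study:

- **Baseline template.** A smooth center-bright ellipsoidal gradient
  (peak 0.8 GMV units at the grid center, falling to 0 at the edges). A
  real brain template would add realism but nothing the downstream
  statistics depend on; the radial gradient keeps the package download-free
  and gives an analytically known analysis mask.
- **Planted effects.** Spheres in voxel space, each `(center, radius_mm,
  magnitude)`; the patient group's baseline is scaled by `1 + magnitude`
  inside the sphere *before* noise and smoothing. Spheres give exactly
  checkable truth masks. The default is two 16 mm-radius spheres at −15%.
  The radius is deliberately twice the 8 mm smoothing FWHM: smoothing
  dilates a suprathreshold region by roughly 2σ ≈ 7 mm beyond the true
  boundary at high contrast-to-noise, so effects at or below the kernel
  scale are unrecoverable *as geometry* even when they are trivially
  detectable — an intrinsic property of smoothed mass-univariate mapping,
  not of this implementation.
- **Cohort.** 62 patients vs 40 controls by default (an elderly male
  PTSD-vs-control design), ages uniform on 60–80, TIV ~ N(1400, 130) mL.
  Age and TIV contribute linear trends (−0.003 GMV/yr, +0.0002 GMV/mL at
  the template peak, scaled by the baseline profile so trends live inside
  the head). Sex is omitted: the emulated cohort is single-sex.
- **Clinical scores.** CAPS is elevated in patients (N(65,15) vs N(4,3));
  MMSE/MoCA/GDS are drawn from the same distribution in both groups. By
  default no score is coupled to the voxel data, so imaging-clinical
  correlations are null by construction (`caps_coupling` turns coupling
  on). Voxel noise is i.i.d. Gaussian (default σ = 0.02) added before
  smoothing; smoothing is applied last, mirroring the usual pipeline order.
- **Determinism.** One `numpy` Generator seeded from the config; identical
  config ⇒ bit-identical cohort.

What the generator does *not* emulate: registration/segmentation error,
spatially varying noise, site effects, non-spherical effect geometry, or
any coupling between atrophy and cognition. Passing tests therefore show
the *statistics* behave as specified under their own assumptions, not that
the pipeline is robust to real-data artifacts.

## VBM group statistics

Per voxel, ordinary least squares of GMV on `[intercept, group, age, TIV]`
with the group factor coded patient = 1; t is the patient-minus-control
contrast over its standard error, p two-sided from Student's t on n − rank
degrees of freedom. Covariates are mean-centered (conditioning only; t is
unchanged). The analysis mask is voxels whose across-subject mean GMV
exceeds 0.1× the global mean. Rank-deficient designs raise an error naming
the collinear columns.

**Smoothing.** Gaussian, σ_vox = FWHM / (2√(2 ln 2)) / voxel size, with
reflecting boundaries — chosen because reflection conserves the total
image sum exactly, which the tests assert at 1e-6 relative.

**Clustering.** Voxels with p < 0.001 (default) are clustered under
26-connectivity (faces + edges + corners), separately per contrast sign;
labels are ordered by descending extent with ties broken by the smallest
linear voxel index, so labeling is deterministic.

**Cluster-extent FWE.** Family-wise error is controlled by permutation
rather than random-field theory: the GLM is refit under random permutations
of the group labels (covariates stay attached to their subjects), and the
null distribution of the *maximum* cluster extent over both signs is
recorded. Each observed cluster gets the add-one estimate
`p = (1 + #{perm max ≥ extent}) / (n_perm + 1)`, which is never 0 and is
exact for exchangeable nulls. Permutation was preferred to random-field
theory because it needs no smoothness estimation, is assumption-light at
desk scale, and its calibration can itself be tested (the suite verifies
the family-wise false-positive rate on null cohorts lands in the binomial
band around 0.05).

**Clinical correlations.** Pearson r with pairwise deletion of missing
scores; a zero-variance input returns an explicitly flagged undefined
result instead of NaN.

## Classification

Features are GMV values at voxels inside FWE-significant clusters, one
column per voxel in linear-index order, with the voxel coordinates kept for
back-projection. Two selection modes exist because the emulated practice is
circular: `paper` mode selects the mask on all subjects before splitting
(reproducing the published workflow, optimistic on null data — the suite
measures this bias); `safe` mode selects on training subjects only.

Six families are benchmarked on one shared stratified 9:1 split: linear and
RBF SVM, random forest, logistic regression, decision tree, and XGBoost
gradient boosting. Hyperparameters come from small fixed grids (SVM
C ∈ {0.1, 1, 10}, RBF γ ∈ {scale, 0.01}; RF trees ∈ {100, 300}, depth
∈ {None, 8}; boosting depth ∈ {2, 3}, learning rate ∈ {0.1, 0.3}; DT depth
∈ {None, 4, 8}), tuned by embedded stratified 10-fold CV maximising
ROC-AUC and refit on the full training set. All features are z-scored with
training-fold statistics inside a Pipeline, for every family, so no test
information reaches the scaler. The positive class is the patient group;
sensitivity is the patient detection rate. Continuous scores are
`predict_proba[:, 1]` where available, else the logistic transform of the
decision function. Benchmark rows sort by accuracy then AUC with a stable
sort, so exact ties resolve to the declared family order.

**Permutation significance.** The test statistic is the *mean held-out AUC
over five independent stratified splits* of the full split→tune→evaluate
procedure; labels are permuted before splitting. The repetition is not
cosmetic: a 10% test set of a ~50-subject cohort holds ~6 subjects, so a
single-split AUC takes few distinct values and a null permutation ties a
perfect observed AUC with probability 1/C(6,2) ≈ 0.067; since ties count
against the observed value in the add-one estimator, attainable p would be
bounded near 0.07 regardless of effect size. Averaging over a few splits
makes the statistic effectively continuous while leaving the permutation
test exact (any statistic is valid under label exchange). `n_splits=1`
recovers the single-split procedure; the null-calibration test uses it to
confirm the p-value is uniform either way.

## Shapley attribution and VICI

Attribution is interventional Shapley value: the coalition value v(S) is
the mean model score over a background sample with the features in S
replaced by the explained subject's values. Two estimators:

- `shapley_exact` — full 2^d enumeration, d ≤ 12; the oracle against which
  everything else is checked (efficiency, symmetry, dummy at 1e-10).
- `shapley_montecarlo` — permutation sampling: per draw, a random feature
  order and a random background row; each feature is credited with the
  change in model score when switched in. Unbiased, O(n_samples · d) model
  evaluations per subject, evaluated in memory-bounded chunks.

The Monte-Carlo estimator reuses *the same draws for every subject*. This
keeps it unbiased and makes each subject's attribution sum telescope to
`f(x_i) − c` with one shared constant c, so rank statistics of the summed
attributions (ROC of the unit-weight composite) match the model's exactly
at any sample budget. The attributed output is the class-1 probability
(or its logistic surrogate), and the background is a seeded subsample of
up to 50 training rows.

**VICI.** The composite index is a weighted sum of per-feature Shapley
values, realized in two coupled forms: a per-subject scalar
`Σ_j w_j φ_ij`, and a per-subject voxel map with `w_j φ_ij` placed at
feature j's voxel (zero elsewhere; map mass equals the scalar). Two
weighting schemes: `unit` (w = 1; default, because it provably makes the
scalar an affine transform of the model output and hence ROC-equivalent to
the classifier) and `importance` (w_j ∝ mean_i |φ_ij|, normalised to sum
1 — the literal "weighted sum" reading; falls back to unit with a warning
if all attributions vanish). The VICI group map feeds the map stack through
the same GLM + permutation-FWE machinery as the GMV data, restricted to
feature voxels with non-degenerate variance. Note the sign convention:
maps attribute toward the *patient* class, so voxels driving patient
classification show patient > control VICI elevation even where GMV itself
is reduced. Abnormality coupling is the Spearman correlation of |t|
between the VICI and GMV maps (voxelwise in the joint mask, or
region-averaged over an atlas); clinical correlations of the scalar are
computed within patients.

## Imaging transcriptomics

The pipeline starts from a donor × region × gene array (probe-level
preprocessing is upstream of this package; the synthetic generator emits
the array directly).

- **Normalization.** Per donor, two passes of the scaled robust sigmoid
  `x ↦ minmax(1/(1 + exp(−(x − median)/(IQR/1.35))))`: across genes within
  each region, then across regions within each gene; output in [0, 1].
  Zero-IQR vectors fall back to rank scaling and are flagged. Each pass is
  monotone along its own axis (ranks preserved per pass; the suite pins
  this down, including the fact that end-to-end rank invariance across
  passes is *not* implied).
- **Differential stability.** DS(gene) = mean over donor pairs of the
  Spearman correlation of the two donors' regional profiles, computed as
  tie-aware Pearson-of-midranks, vectorised over genes. The top 50% by DS
  is retained by default; ties break by gene name.
- **Gene association.** Donor-averaged normalized expression per risk gene
  is Spearman-correlated with the regional group-difference t profile
  (signed by default, |t| by flag), Bonferroni-corrected over the genes
  actually tested; risk genes absent from the array are reported as
  missing, never silently dropped. At least 4 common regions are required.

**Synthetic expression.** Coupled genes share a cross-donor latent profile
correlated with the regional signal; uncoupled genes are independent noise
per donor (hence DS ≈ 0 against DS ≈ c² + noise for coupled genes).
Coupling is planted in *rank space* — the latent mixes the van der Waerden
normal scores of the signal, not the raw signal — so the achieved Spearman
correlation tracks `coupling_strength` for any marginal shape of the
signal, including the heavy-tailed t profiles that group contrasts
produce. The default array holds 10,000 genes with a 34-gene risk panel
containing the 8 coupled genes. The gene count is load-bearing: the
across-gene normalization pass shifts each region's median by
O(n_coupled/n_genes) when coupled genes are present, imprinting a small
negative spatial bias on every other gene (measured mean null ρ ≈ −0.016
at 1,000 genes); at microarray scale the bias is negligible, which is also
why the real workflow is safe. The pipeline aggregates the VICI t map only
over atlas regions actually covered by feature voxels — a mostly-zero
profile would carry one huge tie group and distort rank-correlation
p-values.

The synthetic atlas partitions the analysis mask into spatially compact
parcels by seeded k-means on voxel coordinates.

## Seeds, configuration, IO

A single master seed fans out to per-stage seeds via
`SeedSequence(master).spawn` in a fixed stage order (cohort, vbm, split,
tune, shapley, permutation, expression); every stochastic call takes its
stage seed. The pipeline configuration is one pydantic document (JSON or
YAML) holding every threshold — voxel p 0.001, cluster α 0.05, test
fraction 0.1, 10 CV folds, 1000 permutations, Bonferroni α 0.05, DS
fraction 0.5, 8 mm FWHM — with unknown keys rejected. Volumes are
single-file NIfTI-1 (.nii.gz) with affines preserved bit-exact; tables are
UTF-8 TSV so locale decimal conventions cannot corrupt numbers; blank
clinical cells parse as missing. The thin click CLI (`simulate`, `vbm`,
`classify`, `vici`, `genes`, `all`) wraps the library and writes a
provenance manifest (config hash, per-stage seeds, versions).

## Problem sizes used by the test suite and acceptance script

The default generator scale (40×48×40 voxels at 3 mm, n = 62/40) is the
emulated study condition; the test suite and `scripts/acceptance.py` run
the same code on a 20×24×20 grid with one planted sphere and n = 31/20 —
chosen as the smallest geometry in which a 16 mm effect plus its smoothing
spill fits with margin — with 99–199 permutations, 32 Monte-Carlo draws
per subject for attribution, and 60–200 replicates for the calibration
experiments. Null-calibration replicates for the classifier permutation
test use freshly drawn feature matrices with labels independent of
features, which is distributionally identical to label-shuffling a fixed
cohort and much cheaper than re-simulating volumes per replicate.

## Known limitations

- Permutation FWE assumes exchangeability of subjects under the null;
  covariate effects are refit per permutation (Manly-style) rather than
  residualized (Freedman–Lane), adequate at these scales but approximate.
- The Monte-Carlo Shapley estimator's shared draws correlate estimation
  error across subjects; per-voxel attribution maps at small sample budgets
  are noisy even though subject-level sums are tight.
- The planted-effect setting has a contrast-to-noise ratio far above real
  VBM studies; classifier metrics near 1.0 demonstrate machinery, not
  expected clinical performance.
- DS at two donors is a single correlation, not a stability average; the
  default six donors matches the emulated resource.
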