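"""From Shapley attributions to the volumetric integrated classification
index (VICI): scalar, voxel maps, group map and abnormality coupling.

The classifier's per-voxel Shapley values are summed (unit weights) into a
per-subject scalar that provably ranks subjects exactly like the model, and
back-projected into voxel maps whose group difference is mapped with the
same GLM + permutation FWE machinery as the GMV data.
"""

import numpy as np
from sklearn.metrics import roc_auc_score

from vicikit import classify
from vicikit.shapley import shapley_montecarlo
from vicikit.synthcohort import CohortConfig, simulate_cohort
from vicikit.vbm import DesignSpec, cluster_fwe, significant_mask
from vicikit.vici import abnormality_coupling, compute_vici, vici_clinical, vici_group_map

design = DesignSpec()
cohort = simulate_cohort(
    CohortConfig(
        n_group_a=20, n_group_b=31, shape=(20, 24, 20),
        effect_clusters=[((10, 12, 10), 16.0, -0.15)], noise_sd=0.02, seed=1,
    )
)
fwe = cluster_fwe(cohort.volumes, cohort.subjects, design, n_perm=99, seed=2)
fm = classify.extract_features(
    cohort.volumes, significant_mask(fwe, 0.05), cohort.subjects, design
)
train, _, tr_idx, _ = classify.split_train_test(fm, 0.1, seed=3)
fitted = classify.tune_fit(
    classify.ClassifierSpec("logistic", {"clf__C": [1.0]}, 0), train
)
model_fn = lambda Z: classify.predict_scores(fitted.model, Z)  # noqa: E731

attr = shapley_montecarlo(model_fn, fm.X, fm.X[tr_idx[:30]], n_samples=32, seed=4)
vici = compute_vici(attr, "unit", fm.feature_index, cohort.volumes.shape)

print(f"model AUC: {roc_auc_score(fm.y, model_fn(fm.X)):.6f}")
print(f"VICI  AUC: {roc_auc_score(fm.y, vici.scalar):.6f}  (identical by design)")

group_map = vici_group_map(
    vici, cohort.volumes.affine, cohort.volumes.subject_ids, cohort.subjects,
    design, n_perm=99, seed=5,
)
print("\nVICI group-difference clusters:")
print(group_map.table.round(3).to_string(index=False))

rho, p = abnormality_coupling(group_map.statmap, fwe.statmap)
print(f"\nSpearman |t| coupling between VICI and GMV abnormality: rho={rho:.3f}")

patients = cohort.subjects["group"] == "PTSD"
from vicikit.vici import ViciResult

clin = vici_clinical(
    ViciResult(vici.scalar[patients.to_numpy()], vici.weights, vici.scheme),
    cohort.subjects[patients].reset_index(drop=True),
)
print("\nVICI vs clinical scales (patients only):")
print(clin.round(3).to_string(index=False))
print(
    "\nThe unit-weight VICI scalar reproduces the model's ROC exactly; its\n"
    "voxel maps localise the same region as the GMV contrast (high rho),\n"
    "and, as the scores are simulated independent of voxel noise, it does\n"
    "not correlate with the clinical scales within patients."
)
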