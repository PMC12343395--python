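"""Voxelwise group comparison with permutation cluster-extent FWE correction.

Fits the per-voxel GLM (group + age + TIV), thresholds at voxel p < 0.001,
and corrects cluster extent family-wise with 99 label permutations. The
planted gray-matter reduction should surface as one dominant
patient<control cluster.
"""

import numpy as np

from vicikit.synthcohort import CohortConfig, simulate_cohort
from vicikit.vbm import DesignSpec, cluster_fwe, significant_mask

cohort = simulate_cohort(
    CohortConfig(
        n_group_a=20, n_group_b=31, shape=(20, 24, 20),
        effect_clusters=[((10, 12, 10), 16.0, -0.15)], noise_sd=0.02, seed=1,
    )
)
result = cluster_fwe(
    cohort.volumes, cohort.subjects, DesignSpec(), voxel_p=0.001, n_perm=99, seed=2
)
print(result.table.round(3).to_string(index=False))

mask = significant_mask(result, alpha=0.05)
truth = cohort.truth_mask
dice = 2 * np.sum(mask & truth) / (mask.sum() + truth.sum())
print(f"\nDice(suprathreshold, truth) = {dice:.3f}")
print(
    "\nEach row is one suprathreshold cluster: peak world coordinates (mm),\n"
    "extent in voxels, peak t, and the permutation FWE-corrected p. The\n"
    "patient<control cluster covers the planted sphere; Dice quantifies how\n"
    "well the significant mask recovers the true effect geometry."
)
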