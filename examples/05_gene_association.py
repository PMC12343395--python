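"""Imaging-transcriptomic association with differential-stability filtering.

A synthetic six-donor expression array (400 genes, 8 of them spatially
coupled to the cohort's regional abnormality profile) is normalized with
the two-pass scaled-robust-sigmoid, filtered by differential stability, and
screened for risk-gene association with Bonferroni correction.
"""

import numpy as np

from vicikit import transcriptomics
from vicikit.synthcohort import (
    CohortConfig, ExpressionConfig, simulate_atlas, simulate_cohort,
    simulate_expression,
)
from vicikit.vbm import DesignSpec, default_analysis_mask, fit_glm_tmap

cohort = simulate_cohort(
    CohortConfig(
        n_group_a=20, n_group_b=31, shape=(20, 24, 20),
        effect_clusters=[((10, 12, 10), 16.0, -0.15)], noise_sd=0.02, seed=1,
    )
)
statmap = fit_glm_tmap(cohort.volumes, cohort.subjects, DesignSpec())
atlas = simulate_atlas(default_analysis_mask(cohort.volumes), 118, seed=2)
regional_t = transcriptomics.regional_aggregate(statmap, atlas)
print(f"regional abnormality profile: {regional_t.notna().sum()} regions")

cfg = ExpressionConfig(seed=3)  # 6 donors, 118 regions, 400 genes, 8 coupled
arr = simulate_expression(cfg, regional_t.to_numpy())
norm = transcriptomics.normalize_expression(arr)

ds = transcriptomics.differential_stability(norm)
retained = transcriptomics.select_stable_genes(ds, fraction=0.5)
print(f"differential stability: coupled genes mean DS = "
      f"{ds[arr.coupled_genes].mean():.2f}, others = "
      f"{ds.drop(arr.coupled_genes).mean():.2f}")
print(f"top-50% DS filter retains {len(retained)} genes "
      f"({sum(g in retained for g in arr.coupled_genes)}/8 coupled kept)")

risk_panel = arr.genes[: cfg.n_risk]  # 34 candidate risk genes
table = transcriptomics.gene_vici_association(regional_t, norm, risk_panel)
sig = table[table["significant"]]
print(f"\n{len(sig)} of {len(risk_panel)} risk genes pass Bonferroni at 0.05:")
print(sig[["gene", "rho", "p_bonf"]].round(4).to_string(index=False))
print(
    "\nExactly the planted genes should appear: their regional expression was\n"
    "simulated to track the abnormality profile at Spearman ~0.8, while the\n"
    "remaining genes are spatially random and survive neither the DS filter\n"
    "nor the Bonferroni screen."
)
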