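"""End-to-end orchestration: cohort -> VBM -> classifiers -> VICI -> genes.

One call, :func:`run_pipeline`, chains every stage on a synthetic cohort
with per-stage seeds fanned out from the master seed, and returns all
intermediate results so callers (CLI, scripts, notebooks) can inspect or
persist any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, shapley, transcriptomics, vici
from .config import PipelineConfig
from .synthcohort import (
    ExpressionArray,
    ExpressionConfig,
    SyntheticCohort,
    simulate_atlas,
    simulate_cohort,
    simulate_expression,
)
from .vbm import ClusterResult, DesignSpec, default_analysis_mask

__all__ = ["PipelineResult", "run_pipeline"]

_BACKGROUND_SIZE = 50  # training-set subsample used as attribution background


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: SyntheticCohort
    gmv_clusters: ClusterResult
    features: classify.FeatureMatrix
    benchmark_table: pd.DataFrame
    best_spec: classify.ClassifierSpec
    best_model: object
    best_report: classify.MetricReport
    permutation: classify.PermutationResult
    attributions: shapley.AttributionMatrix
    vici_result: vici.ViciResult
    vici_clusters: ClusterResult
    coupling: tuple[float, float]
    clinical_table: pd.DataFrame
    atlas: np.ndarray
    regional_t: pd.Series
    expression: ExpressionArray
    ds_scores: pd.Series
    gene_table: pd.DataFrame
    extras: dict = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig | None = None,
    design: DesignSpec | None = None,
    shap_samples: int = 64,
) -> PipelineResult:
    """Run the full synthetic-cohort analysis under one configuration.

    ``shap_samples`` controls the Monte-Carlo budget per subject for the
    attribution stage (the estimator reuses draws across subjects, so the
    unit-weight composite stays rank-equivalent to the model output).
    """
    config = config or PipelineConfig()
    design = design or DesignSpec()
    seeds = config.seeds()

    # --- cohort + VBM group difference -----------------------------------
    cohort_cfg = config.cohort.model_copy(update={"seed": seeds["cohort"]})
    cohort = simulate_cohort(cohort_cfg)
    from .vbm import cluster_fwe, significant_mask

    gmv_clusters = cluster_fwe(
        cohort.volumes, cohort.subjects, design,
        voxel_p=config.voxel_p, n_perm=config.n_perm, seed=seeds["vbm"],
    )
    if config.feature_mode == "paper":
        # circular ("published-practice") selection: mask from all subjects
        mask = significant_mask(gmv_clusters, alpha=config.cluster_alpha)
        features = classify.extract_features(
            cohort.volumes, mask, cohort.subjects, design
        )
    else:  # safe: mask from training subjects only
        from sklearn.model_selection import train_test_split as _tts

        y_all = (
            cohort.subjects[design.group_column] == design.patient_label
        ).to_numpy(int)
        train_sel, _ = _tts(
            np.arange(len(y_all)),
            test_size=config.test_fraction,
            stratify=y_all,
            random_state=seeds["split"],
        )
        features, mask = classify.suprathreshold_features(
            cohort.volumes, cohort.subjects, design,
            voxel_p=config.voxel_p, cluster_alpha=config.cluster_alpha,
            n_perm=config.n_perm, seed=seeds["vbm"],
            mode="safe", train_idx=np.sort(train_sel),
        )

    # --- classifier benchmark + significance of the best family ----------
    table = classify.benchmark(
        features,
        classify.default_specs(seeds["tune"]),
        seed=seeds["split"],
        test_fraction=config.test_fraction,
        cv_folds=config.cv_folds,
    )
    best_family = table.iloc[0]["family"]
    best_spec = next(
        s for s in classify.default_specs(seeds["tune"]) if s.family == best_family
    )
    train, test, train_idx, _ = classify.split_train_test(
        features, config.test_fraction, seed=seeds["split"]
    )
    fitted = classify.tune_fit(best_spec, train, cv_folds=config.cv_folds)
    best_report = classify.evaluate(fitted.model, test)
    perm_spec = classify.ClassifierSpec(
        best_spec.family,
        {k: [v] for k, v in fitted.best_params.items()},
        best_spec.seed,
    )
    permutation = classify.permutation_significance(
        perm_spec, features, n_perm=config.n_perm, seed=seeds["permutation"],
        test_fraction=config.test_fraction, cv_folds=config.cv_folds,
    )
    best_report.permutation_p = permutation.p

    # --- Shapley attribution over all subjects ---------------------------
    rng = np.random.default_rng(seeds["shapley"])
    bg_idx = train_idx[
        rng.permutation(len(train_idx))[: min(_BACKGROUND_SIZE, len(train_idx))]
    ]
    model_fn = lambda Z: classify.predict_scores(fitted.model, Z)  # noqa: E731
    attributions = shapley.shapley_montecarlo(
        model_fn,
        features.X,
        features.X[bg_idx],
        n_samples=shap_samples,
        seed=seeds["shapley"],
        background_ids=bg_idx,
    )

    # --- VICI: scalar + maps, group map, coupling, clinical --------------
    vici_result = vici.compute_vici(
        attributions,
        scheme=config.vici_scheme,
        feature_index=features.feature_index,
        volume_shape=cohort.volumes.shape,
    )
    vici_clusters = vici.vici_group_map(
        vici_result,
        cohort.volumes.affine,
        cohort.volumes.subject_ids,
        cohort.subjects,
        design,
        voxel_p=config.voxel_p,
        n_perm=config.n_perm,
        seed=seeds["vbm"],
    )
    coupling = vici.abnormality_coupling(vici_clusters.statmap, gmv_clusters.statmap)
    patients = cohort.subjects[design.group_column] == design.patient_label
    clinical_table = vici.vici_clinical(
        vici.ViciResult(
            scalar=vici_result.scalar[patients.to_numpy()],
            weights=vici_result.weights,
            scheme=vici_result.scheme,
        ),
        cohort.subjects[patients].reset_index(drop=True),
    )

    # --- imaging transcriptomics -----------------------------------------
    analysis_mask = default_analysis_mask(cohort.volumes)
    atlas = simulate_atlas(
        analysis_mask, config.expression.n_regions, seed=seeds["expression"]
    )
    # Aggregate VICI t over regions the feature set actually covers; regions
    # with no covered voxel stay missing (a mostly-zero profile would carry a
    # huge tie group and distort rank-correlation p-values downstream).
    regional_t = transcriptomics.regional_aggregate(vici_clusters.statmap, atlas)
    covered = regional_t.dropna()
    if len(covered) < 4:
        raise RuntimeError(
            f"only {len(covered)} atlas regions covered by feature voxels; "
            "need >= 4 for gene association — use more/larger atlas regions"
        )
    expr_cfg = config.expression.model_copy(
        update={"seed": seeds["expression"], "n_regions": len(covered)}
    )
    expression = simulate_expression(expr_cfg, covered.to_numpy())
    expression.regions = list(covered.index)
    normalized = transcriptomics.normalize_expression(expression)
    ds_scores = transcriptomics.differential_stability(normalized)
    retained = transcriptomics.select_stable_genes(ds_scores, config.ds_fraction)
    risk_genes = list(expression.genes[: expr_cfg.n_risk])
    gene_table = transcriptomics.gene_vici_association(
        regional_t,
        normalized,
        risk_genes,
        alpha=config.bonferroni_alpha,
    )

    return PipelineResult(
        config=config,
        cohort=cohort,
        gmv_clusters=gmv_clusters,
        features=features,
        benchmark_table=table,
        best_spec=best_spec,
        best_model=fitted.model,
        best_report=best_report,
        permutation=permutation,
        attributions=attributions,
        vici_result=vici_result,
        vici_clusters=vici_clusters,
        coupling=coupling,
        clinical_table=clinical_table,
        atlas=atlas,
        regional_t=regional_t,
        expression=expression,
        ds_scores=ds_scores,
        gene_table=gene_table,
        extras={"feature_mask": mask, "retained_genes": retained},
    )
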