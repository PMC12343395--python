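"""The volumetric integrated classification index (VICI).

VICI condenses per-feature Shapley attributions of a GMV classifier into a
single interpretable quantity, in two coupled forms:

* a per-subject scalar — the weighted sum of that subject's Shapley values,
  VICI_i = sum_j w_j * phi_ij;
* a per-subject voxel map — the weighted Shapley field back-projected to the
  voxels the features came from.

Weighting schemes: ``unit`` (w_j = 1; the scalar is then exactly the model
output minus its base value, so VICI is ROC-equivalent to the classifier)
and ``importance`` (w_j proportional to the mean |phi_.j| across subjects,
normalised to sum 1 — the literal "weighted sum" reading).

Interpretability analyses: VICI group-difference mapping (delegating to the
VBM GLM + permutation-FWE machinery), Spearman coupling between VICI and GMV
abnormality maps, and clinical-score correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .shapley import AttributionMatrix
from .vbm import (
    ClusterResult,
    DesignSpec,
    StatMap,
    VolumeStack,
    clinical_correlation,
    cluster_fwe,
)

__all__ = [
    "ViciResult",
    "compute_vici",
    "vici_group_map",
    "abnormality_coupling",
    "vici_clinical",
]


@dataclass
class ViciResult:
    scalar: np.ndarray  # (n_subjects,)
    weights: np.ndarray  # (n_features,)
    scheme: str
    maps: np.ndarray | None = None  # (n_subjects, X, Y, Z) or None
    feature_index: np.ndarray | None = None
    base_value: float = 0.0


def compute_vici(
    attr: AttributionMatrix,
    scheme: str = "unit",
    feature_index: np.ndarray | None = None,
    volume_shape: tuple[int, int, int] | None = None,
) -> ViciResult:
    """Weighted summation of Shapley values into scalar and (optional) maps.

    unit: w_j = 1 for all features (pure additive decomposition);
    importance: w_j = mean_i |phi_ij| normalised to sum 1. All-zero
    attributions under the importance scheme fall back to unit weights with
    a warning. Voxel maps are produced when ``feature_index`` and
    ``volume_shape`` are given; voxels outside the feature set stay 0.
    """
    phi = attr.phi
    if scheme == "unit":
        weights = np.ones(phi.shape[1])
    elif scheme == "importance":
        mean_abs = np.abs(phi).mean(axis=0)
        total = mean_abs.sum()
        if total == 0:
            warnings.warn(
                "all attributions are zero; importance weights undefined — "
                "falling back to unit weights",
                stacklevel=2,
            )
            weights, scheme = np.ones(phi.shape[1]), "unit"
        else:
            weights = mean_abs / total
    else:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    scalar = phi @ weights
    maps = None
    if feature_index is not None and volume_shape is not None:
        feature_index = np.asarray(feature_index, dtype=int)
        maps = np.zeros((phi.shape[0],) + tuple(volume_shape))
        flat = np.ravel_multi_index(feature_index.T, volume_shape)
        maps.reshape(phi.shape[0], -1)[:, flat] = phi * weights
    return ViciResult(
        scalar=scalar,
        weights=weights,
        scheme=scheme,
        maps=maps,
        feature_index=feature_index,
        base_value=attr.base_value,
    )


def vici_group_map(
    result: ViciResult,
    affine: np.ndarray,
    subject_ids: list[str],
    subjects: pd.DataFrame,
    design: DesignSpec,
    voxel_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Group-difference t-map of the per-subject VICI maps, FWE-corrected.

    Delegates to the same GLM and permutation cluster-extent machinery used
    for GMV, restricted to feature voxels with non-degenerate variance.
    """
    if result.maps is None:
        raise ValueError("ViciResult has no maps; compute_vici needs feature_index")
    stack = VolumeStack(result.maps, affine, list(subject_ids))
    mask = stack.data.var(axis=0) > 0
    if not mask.any():
        empty = pd.DataFrame(
            columns=["contrast", "x", "y", "z", "extent", "peak_t", "fwe_p"]
        )
        statmap = StatMap(
            t=np.zeros(stack.shape),
            p_unc=np.ones(stack.shape),
            df=max(stack.n_subjects - 2, 1),
            mask=mask,
            affine=stack.affine,
        )
        return ClusterResult(empty, statmap, [], np.zeros(n_perm, dtype=int), n_perm)
    return cluster_fwe(
        stack, subjects, design, voxel_p=voxel_p, n_perm=n_perm, seed=seed, mask=mask
    )


def abnormality_coupling(
    vici_t: StatMap,
    gmv_t: StatMap,
    level: str = "voxel",
    atlas: np.ndarray | None = None,
) -> tuple[float, float]:
    """Spearman correlation between |t| abnormality profiles.

    voxel level correlates the voxelwise |t| values inside the joint mask;
    region level first averages |t| within atlas labels. Returns (rho, p).
    """
    if vici_t.t.shape != gmv_t.t.shape:
        raise ValueError("stat maps do not share a voxel grid")
    joint = vici_t.mask & gmv_t.mask
    if level == "voxel":
        a = np.abs(vici_t.t[joint])
        b = np.abs(gmv_t.t[joint])
    elif level == "region":
        if atlas is None:
            raise ValueError("region level requires an atlas volume")
        from .transcriptomics import regional_aggregate

        abs_v = StatMap(np.abs(vici_t.t), vici_t.p_unc, vici_t.df, joint, vici_t.affine)
        abs_g = StatMap(np.abs(gmv_t.t), gmv_t.p_unc, gmv_t.df, joint, gmv_t.affine)
        ra = regional_aggregate(abs_v, atlas)
        rb = regional_aggregate(abs_g, atlas)
        common = ra.dropna().index.intersection(rb.dropna().index)
        a, b = ra[common].to_numpy(), rb[common].to_numpy()
    else:
        raise ValueError("level must be 'voxel' or 'region'")
    if len(a) < 3:
        raise ValueError(f"need >= 3 units to correlate, got {len(a)}")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def vici_clinical(
    result: ViciResult,
    subjects: pd.DataFrame,
    scores: tuple[str, ...] = ("caps", "mmse", "moca", "gds"),
) -> pd.DataFrame:
    """Pearson correlations between the VICI scalar and clinical scores."""
    rows = []
    for score in scores:
        res = clinical_correlation(result.scalar, subjects, score)
        rows.append(
            {
                "score": score,
                "r": np.nan if res.undefined else res.r,
                "p": np.nan if res.undefined else res.p,
                "n": res.n,
                "undefined": res.undefined,
            }
        )
    return pd.DataFrame(rows)
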