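"""Mass-univariate group statistics on gray-matter-volume (GMV) stacks.

Implements the classical voxel-based-morphometry (VBM) group pipeline:
a per-voxel ordinary-least-squares GLM with nuisance covariates, two-sided
t / p maps, suprathreshold clustering under 26-connectivity, cluster-extent
family-wise-error (FWE) correction by sign-flipping-free group-label
permutation, Gaussian smoothing, and Pearson correlations between imaging
scalars and clinical scores.

Conventions
-----------
* The group contrast is always *patient minus control*, so gray-matter
  reduction in patients appears as negative t.
* Two-sided voxel p-values; positive and negative excursions are clustered
  separately and both enter the same permutation family (the null
  distribution records the maximum extent over both signs).
* Cluster FWE p uses the add-one permutation estimator
  ``(1 + #{perm max extent >= observed}) / (n_perm + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "VolumeStack",
    "DesignSpec",
    "StatMap",
    "Cluster",
    "ClusterResult",
    "CorrelationResult",
    "smooth_gaussian",
    "default_analysis_mask",
    "fit_glm_tmap",
    "threshold_clusters",
    "cluster_fwe",
    "significant_mask",
    "clinical_correlation",
]

# 26-connectivity: faces + edges + corners, the SPM-compatible neighbourhood
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VolumeStack:
    """Subjects x X x Y x Z stack of GMV volumes sharing one affine."""

    data: np.ndarray
    affine: np.ndarray
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("VolumeStack.data must be 4-D (subjects, X, Y, Z)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.subject_ids)} subject ids for {self.data.shape[0]} volumes"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def voxel_size_mm(self) -> float:
        """Isotropic voxel size derived from the affine."""
        sizes = np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))
        if not np.allclose(sizes, sizes[0], rtol=1e-6):
            raise ValueError(f"anisotropic voxels not supported: {sizes}")
        return float(sizes[0])

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (n, 3) to world mm coordinates."""
        ijk = np.atleast_2d(ijk)
        hom = np.c_[ijk, np.ones(len(ijk))]
        return (self.affine @ hom.T).T[:, :3]


@dataclass(frozen=True)
class DesignSpec:
    """Two-group GLM design: group factor plus nuisance covariates.

    ``patient_label`` names the level of ``group_column`` coded 1 in the
    design; the contrast is the patient-minus-control group effect.
    """

    group_column: str = "group"
    patient_label: str = "PTSD"
    covariates: tuple[str, ...] = ("age", "tiv")
    contrast: str = "patient-control"


@dataclass
class StatMap:
    """Voxelwise t / two-sided p images with analysis mask and df."""

    t: np.ndarray
    p_unc: np.ndarray
    df: int
    mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.t[self.mask])):
            raise ValueError("non-finite t inside mask")


@dataclass(frozen=True)
class Cluster:
    sign: int  # +1 / -1 excursion direction
    voxels: np.ndarray  # (extent, 3) 0-based voxel indices
    extent: int
    peak_t: float
    peak_ijk: tuple[int, int, int]


@dataclass
class ClusterResult:
    """Observed clusters with permutation FWE p-values."""

    table: pd.DataFrame
    statmap: StatMap
    clusters: list[Cluster]
    null_max_extent: np.ndarray
    n_perm: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    p: float | None
    n: int
    undefined: bool = False


def smooth_gaussian(stack: VolumeStack, fwhm_mm: float) -> VolumeStack:
    """Gaussian-smooth every volume at the given FWHM (mm).

    sigma_vox = fwhm / (2 sqrt(2 ln 2)) / voxel_size. Reflecting boundary
    conditions conserve the total image sum exactly.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return VolumeStack(stack.data.copy(), stack.affine.copy(), list(stack.subject_ids))
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / stack.voxel_size_mm
    out = np.empty_like(stack.data)
    for i in range(stack.n_subjects):
        ndimage.gaussian_filter(stack.data[i], sigma, output=out[i], mode="reflect")
    return VolumeStack(out, stack.affine.copy(), list(stack.subject_ids))


def default_analysis_mask(stack: VolumeStack) -> np.ndarray:
    """Voxels whose across-subject mean GMV exceeds 0.1x the global mean."""
    mean_img = stack.data.mean(axis=0)
    return mean_img > 0.1 * mean_img.mean()


def _design_matrix(
    subjects: pd.DataFrame, design: DesignSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Build [intercept, group, covariates...]; returns (X, contrast, names)."""
    groups = subjects[design.group_column].to_numpy()
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {list(levels)}")
    if design.patient_label not in levels:
        raise ValueError(
            f"patient label {design.patient_label!r} absent from column "
            f"{design.group_column!r} (levels {list(levels)})"
        )
    g = (groups == design.patient_label).astype(float)
    for lab, cnt in zip(*np.unique(groups, return_counts=True)):
        if cnt < 2:
            raise ValueError(f"group {lab!r} has {cnt} subject(s); need >= 2")
    cols = [np.ones(len(subjects)), g]
    names = ["intercept", "group"]
    for cov in design.covariates:
        x = subjects[cov].to_numpy(dtype=float)
        cols.append(x - x.mean())  # centering: conditioning only, t unchanged
        names.append(cov)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the offending columns for the error message
        bad = []
        for j in range(1, X.shape[1]):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(names[j])
        raise ValueError(f"design matrix rank deficient; collinear column(s): {bad}")
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return X, contrast, names


def _glm_t(X: np.ndarray, Y: np.ndarray, contrast: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorised OLS t-statistics for one contrast over many voxels.

    Y is (n_subjects, n_voxels). Returns (t per voxel, residual df).
    """
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, k={k})")
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    c_var = float(contrast @ xtx_inv @ contrast)
    se = np.sqrt(np.maximum(sigma2 * c_var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (contrast @ beta) / se, 0.0)
    return t, df


def fit_glm_tmap(
    stack: VolumeStack,
    subjects: pd.DataFrame,
    design: DesignSpec,
    mask: np.ndarray | None = None,
) -> StatMap:
    """Per-voxel OLS of GMV on [intercept, group, covariates]; two-sided p.

    ``mask`` restricts the analysis; by default voxels with mean GMV above
    0.1x the global mean are analysed. Outside the mask t = 0 and p = 1.
    """
    if len(subjects) != stack.n_subjects:
        raise ValueError("subject table and volume stack are not aligned")
    if mask is None:
        mask = default_analysis_mask(stack)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {stack.shape}")
    X, contrast, _ = _design_matrix(subjects, design)
    Y = stack.data.reshape(stack.n_subjects, -1)[:, mask.ravel()]
    t_masked, df = _glm_t(X, Y, contrast)
    p_masked = 2.0 * stats.t.sf(np.abs(t_masked), df)
    # p=0 would violate the (0, 1] contract at extreme t; clamp to tiny
    p_masked = np.maximum(p_masked, np.finfo(float).tiny)
    t = np.zeros(stack.shape)
    p = np.ones(stack.shape)
    t.ravel()[mask.ravel()] = t_masked
    p.ravel()[mask.ravel()] = p_masked
    return StatMap(t=t, p_unc=p, df=df, mask=mask, affine=stack.affine.copy())


def threshold_clusters(
    statmap: StatMap,
    voxel_p: float = 0.001,
    connectivity: int = 26,
) -> list[Cluster]:
    """Connected components of suprathreshold voxels, per contrast sign.

    Voxels with p_unc < ``voxel_p`` are clustered under the chosen
    neighbourhood (26 = faces+edges+corners, 6 = faces only), separately for
    t > 0 and t < 0. Clusters are ordered by descending extent, ties broken
    by the smallest linear voxel index.
    """
    if not 0.0 < voxel_p < 1.0:
        raise ValueError(f"voxel_p must be in (0, 1), got {voxel_p}")
    if connectivity == 26:
        struct = _STRUCT_26
    elif connectivity == 6:
        struct = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    supra = (statmap.p_unc < voxel_p) & statmap.mask
    clusters: list[Cluster] = []
    for sign in (-1, 1):
        excursion = supra & ((statmap.t < 0) if sign < 0 else (statmap.t > 0))
        labels, n_lab = ndimage.label(excursion, structure=struct)
        for lab in range(1, n_lab + 1):
            vox = np.argwhere(labels == lab)
            tvals = statmap.t[tuple(vox.T)]
            peak = vox[np.argmax(np.abs(tvals))]
            clusters.append(
                Cluster(
                    sign=sign,
                    voxels=vox,
                    extent=len(vox),
                    peak_t=float(tvals[np.argmax(np.abs(tvals))]),
                    peak_ijk=tuple(int(v) for v in peak),
                )
            )
    shape = statmap.t.shape

    def _min_linear(c: Cluster) -> int:
        return int(np.ravel_multi_index(c.voxels.T, shape).min())

    clusters.sort(key=lambda c: (-c.extent, _min_linear(c)))
    return clusters


def _max_cluster_extent(
    t: np.ndarray, df: int, mask: np.ndarray, voxel_p: float, struct: np.ndarray
) -> int:
    """Largest suprathreshold cluster extent over both signs (0 if none)."""
    t_crit = stats.t.isf(voxel_p / 2.0, df)
    supra = (np.abs(t) > t_crit) & mask
    best = 0
    for excursion in (supra & (t < 0), supra & (t > 0)):
        labels, n_lab = ndimage.label(excursion, structure=struct)
        if n_lab:
            best = max(best, int(np.bincount(labels.ravel())[1:].max()))
    return best


def cluster_fwe(
    stack: VolumeStack,
    subjects: pd.DataFrame,
    design: DesignSpec,
    voxel_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    mask: np.ndarray | None = None,
    connectivity: int = 26,
) -> ClusterResult:
    """Cluster-extent FWE correction by group-label permutation.

    The null distribution of the maximum cluster extent (over both contrast
    signs) is built by refitting the GLM under ``n_perm`` random permutations
    of the group labels, covariates kept fixed with their subjects. Each
    observed cluster receives FWE p = (1 + #{perm max >= extent}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if mask is None:
        mask = default_analysis_mask(stack)
    observed = fit_glm_tmap(stack, subjects, design, mask=mask)
    clusters = threshold_clusters(observed, voxel_p=voxel_p, connectivity=connectivity)

    struct = _STRUCT_26 if connectivity == 26 else ndimage.generate_binary_structure(3, 1)
    X, contrast, _ = _design_matrix(subjects, design)
    flat_mask = mask.ravel()
    Y = stack.data.reshape(stack.n_subjects, -1)[:, flat_mask]
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=int)
    t_full = np.zeros(stack.shape)
    group_col = X[:, 1].copy()
    for b in range(n_perm):
        Xp = X.copy()
        Xp[:, 1] = rng.permutation(group_col)
        tb, df = _glm_t(Xp, Y, contrast)
        t_full.ravel()[flat_mask] = tb
        null_max[b] = _max_cluster_extent(t_full, df, mask, voxel_p, struct)

    rows = []
    for c in clusters:
        fwe_p = (1 + int((null_max >= c.extent).sum())) / (n_perm + 1)
        world = observed.affine @ np.r_[c.peak_ijk, 1.0]
        rows.append(
            {
                "contrast": "patient<control" if c.sign < 0 else "patient>control",
                "x": world[0],
                "y": world[1],
                "z": world[2],
                "extent": c.extent,
                "peak_t": c.peak_t,
                "fwe_p": fwe_p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["contrast", "x", "y", "z", "extent", "peak_t", "fwe_p"]
    )
    if len(table):
        table = table.sort_values(
            ["fwe_p", "extent"], ascending=[True, False], kind="stable"
        ).reset_index(drop=True)
    return ClusterResult(
        table=table,
        statmap=observed,
        clusters=clusters,
        null_max_extent=null_max,
        n_perm=n_perm,
    )


def significant_mask(
    result: ClusterResult, alpha: float = 0.05, sign: int | None = None
) -> np.ndarray:
    """Union of voxels in clusters with FWE p < alpha (optionally one sign)."""
    out = np.zeros(result.statmap.t.shape, dtype=bool)
    for c in result.clusters:
        if sign is not None and c.sign != sign:
            continue
        fwe_p = (1 + int((result.null_max_extent >= c.extent).sum())) / (result.n_perm + 1)
        if fwe_p < alpha:
            out[tuple(c.voxels.T)] = True
    return out


def clinical_correlation(
    values: Sequence[float] | np.ndarray,
    subjects: pd.DataFrame,
    score_name: str,
) -> CorrelationResult:
    """Pearson correlation of a per-subject scalar with a clinical score.

    Missing scores (NaN) are dropped pairwise; n reports the pairs used.
    Zero variance in either variable yields an explicitly undefined result
    rather than NaN propagation.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(subjects):
        raise ValueError("values and subject table are not aligned")
    score = subjects[score_name].to_numpy(dtype=float)
    keep = np.isfinite(values) & np.isfinite(score)
    v, s = values[keep], score[keep]
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"need >= 3 paired non-missing observations, got {n}")
    if np.std(v) == 0 or np.std(s) == 0:
        return CorrelationResult(r=None, p=None, n=n, undefined=True)
    r, p = stats.pearsonr(v, s)
    return CorrelationResult(r=float(r), p=float(p), n=n)
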