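"""Imaging-transcriptomic association of regional abnormality with expression.

Starting from a donor x region x gene expression array (microarray-style
values already mapped to parcels), the pipeline applies the standard
two-pass scaled-robust-sigmoid (SRS) normalization (across genes within each
region, then across regions within each gene, per donor), filters genes by
differential stability (mean inter-donor Spearman correlation of regional
profiles), and tests candidate risk genes for Spearman association between
their donor-averaged regional expression and a regional t-statistic profile,
with Bonferroni correction over the tested genes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .synthcohort import ExpressionArray
from .vbm import StatMap

__all__ = [
    "regional_aggregate",
    "normalize_expression",
    "differential_stability",
    "select_stable_genes",
    "gene_vici_association",
]


def regional_aggregate(statmap: StatMap, atlas: np.ndarray) -> pd.Series:
    """Mean t per atlas region (labels > 0), inside the analysis mask.

    Regions with no masked voxels are NaN (flagged missing, not dropped).
    """
    atlas = np.asarray(atlas)
    if atlas.shape != statmap.t.shape:
        raise ValueError(f"atlas shape {atlas.shape} != map shape {statmap.t.shape}")
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    out = {}
    for lab in labels:
        sel = (atlas == lab) & statmap.mask
        out[int(lab)] = float(statmap.t[sel].mean()) if sel.any() else np.nan
    return pd.Series(out, name="mean_t").rename_axis("region")


def _srs(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scaled robust sigmoid of a vector -> [0, 1]; rank fallback on zero IQR.

    s(x) = 1 / (1 + exp(-(x - median) / (IQR / 1.35))), then min-max scaled.
    Both the sigmoid and the fallback (ranks scaled to [0, 1]) are monotone,
    so within-vector rank order is preserved.
    """
    med = np.median(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr == 0:
        if np.ptp(x) == 0:
            return np.full_like(x, 0.5, dtype=float), True
        ranks = stats.rankdata(x)
        return (ranks - 1) / (len(x) - 1), True
    s = 1.0 / (1.0 + np.exp(-(x - med) / (iqr / 1.35)))
    lo, hi = s.min(), s.max()
    return (s - lo) / (hi - lo) if hi > lo else np.full_like(s, 0.5), False


def _srs_along(x: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised SRS along one axis of a 2-D array.

    Returns (normalised array, boolean fallback mask over the other axis).
    Vectors with zero IQR are redone with the scalar rank fallback.
    """
    med = np.median(x, axis=axis, keepdims=True)
    q75 = np.percentile(x, 75, axis=axis, keepdims=True)
    q25 = np.percentile(x, 25, axis=axis, keepdims=True)
    iqr = q75 - q25
    safe = np.where(iqr > 0, iqr, 1.0)
    s = 1.0 / (1.0 + np.exp(-(x - med) / (safe / 1.35)))
    lo = s.min(axis=axis, keepdims=True)
    hi = s.max(axis=axis, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    out = np.where(hi > lo, (s - lo) / span, 0.5)
    fallback = np.squeeze(iqr == 0, axis=axis)
    if fallback.any():
        for idx in np.flatnonzero(fallback):
            sel = (slice(None), idx) if axis == 0 else (idx, slice(None))
            out[sel], _ = _srs(x[sel])
    return out, fallback


def normalize_expression(arr: ExpressionArray) -> ExpressionArray:
    """Two-pass SRS normalization, independently per donor.

    Pass 1 normalises each region's sample across genes; pass 2 normalises
    each gene across regions. Output lies in [0, 1]; genes whose second pass
    required the rank fallback (zero IQR) are recorded in ``rank_fallback``.
    """
    if arr.values.shape[1] < 2:
        raise ValueError("need >= 2 regions to normalize across")
    out = np.empty_like(arr.values)
    fallback: set[str] = set()
    for d in range(arr.values.shape[0]):
        stage, _ = _srs_along(arr.values[d], axis=1)  # per region, across genes
        out[d], gene_fb = _srs_along(stage, axis=0)  # per gene, across regions
        fallback.update(arr.genes[g] for g in np.flatnonzero(gene_fb))
    return replace(arr, values=out, rank_fallback=fallback)


def differential_stability(arr: ExpressionArray) -> pd.Series:
    """DS per gene: mean over donor pairs of the Spearman correlation
    between the two donors' regional profiles.

    Spearman is computed as the Pearson correlation of midranks (tie-aware),
    vectorised over genes; a constant profile contributes 0 to its pairs.
    """
    nd, nr, _ = arr.values.shape
    if nd < 2:
        raise ValueError("differential stability needs >= 2 donors")
    ranks = stats.rankdata(arr.values, axis=1)
    z = ranks - ranks.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, keepdims=True)
    z = np.where(sd > 0, z / np.where(sd > 0, sd, 1.0), 0.0)
    pair_sum = np.zeros(arr.values.shape[2])
    n_pairs = 0
    for a in range(nd):
        for b in range(a + 1, nd):
            rho = np.einsum("rg,rg->g", z[a], z[b]) / nr
            # identical rank profiles have rho = 1 by definition; the dot
            # product can land 1 ulp away, so restore exactness there
            rho[(ranks[a] == ranks[b]).all(axis=0) & (sd[a, 0] > 0)] = 1.0
            pair_sum += rho
            n_pairs += 1
    ds = pair_sum / n_pairs
    return pd.Series(ds, index=pd.Index(arr.genes, name="gene"), name="ds")


def select_stable_genes(ds: pd.Series, fraction: float = 0.5) -> list[str]:
    """Top ``fraction`` of genes by DS; ties broken by gene name."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    k = max(1, int(round(fraction * len(ds))))
    order = sorted(ds.index, key=lambda g: (-ds[g], g))
    return order[:k]


def gene_vici_association(
    regional_t: pd.Series,
    arr: ExpressionArray,
    risk_genes: list[str],
    alpha: float = 0.05,
    use_abs: bool = False,
) -> pd.DataFrame:
    """Spearman association of risk-gene expression with regional t.

    Expression is averaged across donors per gene and correlated with the
    (signed, or absolute if ``use_abs``) regional t profile over the common
    non-missing regions. Bonferroni corrects over the genes actually tested;
    risk genes absent from the array are reported with present=False rather
    than silently dropped. Sorted by corrected p.
    """
    gene_pos = {g: i for i, g in enumerate(arr.genes)}
    present = [g for g in risk_genes if g in gene_pos]
    region_pos = {r: i for i, r in enumerate(arr.regions)}
    t_clean = regional_t.dropna()
    common = [r for r in t_clean.index if r in region_pos]
    if not common:
        raise ValueError("no regions shared between the t profile and the array")
    if len(common) < 4:
        raise ValueError(f"need >= 4 common regions, got {len(common)}")
    t_vec = t_clean[common].to_numpy(dtype=float)
    if use_abs:
        t_vec = np.abs(t_vec)
    ridx = [region_pos[r] for r in common]
    mean_expr = arr.values.mean(axis=0)  # regions x genes, donor-averaged
    m = len(present)
    rows = []
    for g in risk_genes:
        if g not in gene_pos:
            rows.append(
                {"gene": g, "rho": np.nan, "p": np.nan, "p_bonf": np.nan,
                 "significant": False, "present": False}
            )
            continue
        expr = mean_expr[ridx, gene_pos[g]]
        rho, p = stats.spearmanr(t_vec, expr)
        if np.isnan(rho):  # constant expression profile
            rho, p = 0.0, 1.0
        p_bonf = min(1.0, p * m)
        rows.append(
            {"gene": g, "rho": float(rho), "p": float(p), "p_bonf": float(p_bonf),
             "significant": bool(p_bonf < alpha), "present": True}
        )
    table = pd.DataFrame(rows)
    return table.sort_values(
        ["p_bonf", "gene"], kind="stable", na_position="last"
    ).reset_index(drop=True)
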