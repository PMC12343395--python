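"""Seeded synthetic case-control cohorts for the VBM / VICI pipeline.

The generator emulates the statistical structure of a preprocessed,
modulated, smoothed gray-matter-volume (GMV) study: a two-group cohort with
spherical hypo-volume effects planted in the patient group, linear age and
head-size (TIV) trends, clinical scores, and a multi-donor region x gene
expression array with a configurable subset of genes spatially coupled to a
regional signal.

Defaults mirror an elderly male PTSD case-control study: 62 patients vs 40
controls aged 60-80, 8 mm FWHM smoothing, CAPS elevated in patients and
cognitive scales matched between groups. Volumes are 40x48x40 at 3 mm
(a desk-scale whole-head grid); the baseline template is a smooth
center-bright radial gradient rather than a real brain template, keeping the
artifact download-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .vbm import VolumeStack, smooth_gaussian

__all__ = [
    "CohortConfig",
    "ExpressionConfig",
    "SyntheticCohort",
    "ExpressionArray",
    "simulate_cohort",
    "simulate_expression",
    "simulate_atlas",
    "write_cohort",
]

# (center voxel ijk, radius mm, magnitude as fraction of baseline GMV).
# Two roughly bilateral anterior spheres; radius 16 mm = 2x the default
# smoothing FWHM so the planted geometry survives an 8 mm kernel.
_DEFAULT_CLUSTERS: list[tuple[tuple[int, int, int], float, float]] = [
    ((13, 33, 24), 16.0, -0.15),
    ((27, 33, 24), 16.0, -0.15),
]


class CohortConfig(BaseModel):
    """Configuration of one synthetic GMV cohort (group A = controls)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_group_a: int = Field(default=40, ge=2, description="controls")
    n_group_b: int = Field(default=62, ge=2, description="patients")
    shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = Field(default=3.0, gt=0)
    effect_clusters: list[tuple[tuple[int, int, int], float, float]] = Field(
        default_factory=lambda: [tuple(c) for c in _DEFAULT_CLUSTERS]
    )
    age_range: tuple[float, float] = (60.0, 80.0)
    age_slope: float = -0.003  # GMV units per year
    tiv_slope: float = 0.0002  # GMV units per mL
    noise_sd: float = Field(default=0.02, ge=0)
    smooth_fwhm_mm: float = Field(default=8.0, ge=0)
    caps_coupling: float = 0.0  # optional CAPS <-> planted-effect coupling
    baseline_peak: float = 0.8  # GMV at template center
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if any(s < 1 for s in self.shape):
            raise ValueError(f"degenerate volume shape {self.shape}")
        for center, radius, _mag in self.effect_clusters:
            if radius <= 0:
                raise ValueError(f"cluster radius must be > 0, got {radius}")
            if any(not 0 <= c < s for c, s in zip(center, self.shape)):
                raise ValueError(f"cluster center {center} outside grid {self.shape}")
        if self.age_range[1] < self.age_range[0]:
            raise ValueError(f"empty age range {self.age_range}")
        return self


class ExpressionConfig(BaseModel):
    """Configuration of a synthetic multi-donor region x gene array."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    n_donors: int = Field(default=6, ge=2)
    n_regions: int = Field(default=118, ge=2)
    # microarray-scale gene count: the across-gene normalization pass shifts
    # every region's median by O(n_coupled / n_genes) when coupled genes are
    # present, imprinting a small negative spatial bias on all other genes;
    # at 10^4 genes (the scale of the resource this emulates) it is negligible
    n_genes: int = Field(default=10_000, ge=1)
    n_coupled: int = Field(default=8, ge=0)
    # candidate risk-gene panel size: the first n_risk genes (which include
    # the n_coupled planted genes) play the role of a GWAS risk-gene list
    n_risk: int = Field(default=34, ge=1)
    coupling_strength: float = Field(default=0.8, ge=-1.0, le=1.0)
    noise_sd: float = Field(default=0.5, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ExpressionConfig":
        if self.n_coupled > self.n_genes:
            raise ValueError("n_coupled cannot exceed n_genes")
        if not self.n_coupled <= self.n_risk <= self.n_genes:
            raise ValueError("need n_coupled <= n_risk <= n_genes")
        return self


@dataclass
class SyntheticCohort:
    volumes: VolumeStack
    subjects: pd.DataFrame
    truth_mask: np.ndarray
    config: CohortConfig


@dataclass
class ExpressionArray:
    """Donor x region x gene expression values.

    ``coupled_genes`` is generator truth metadata (synthetic arrays only);
    ``rank_fallback`` flags genes whose normalization fell back to ranks.
    """

    values: np.ndarray  # (n_donors, n_regions, n_genes)
    donors: list[str]
    regions: list[int]
    genes: list[str]
    coupled_genes: list[str] | None = None
    rank_fallback: set[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("expression values must be donor x region x gene")
        nd, nr, ng = self.values.shape
        if (nd, nr, ng) != (len(self.donors), len(self.regions), len(self.genes)):
            raise ValueError("axis labels do not match value dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression values")


def _baseline_template(config: CohortConfig) -> np.ndarray:
    """Center-bright ellipsoidal gradient: peak GMV at center, ~0 at edges."""
    idx = np.indices(config.shape, dtype=float)
    center = (np.array(config.shape, dtype=float) - 1) / 2.0
    semi = 0.48 * np.array(config.shape, dtype=float)  # semi-axes in voxels
    rho2 = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return config.baseline_peak * np.clip(1.0 - rho2, 0.0, None)


def _effect_field(config: CohortConfig) -> np.ndarray:
    """Sum of spherical fractional-change fields (patient group only)."""
    idx = np.indices(config.shape, dtype=float)
    field = np.zeros(config.shape)
    for center, radius_mm, magnitude in config.effect_clusters:
        d2 = sum((idx[i] - center[i]) ** 2 for i in range(3)) * config.voxel_size_mm**2
        field += magnitude * (d2 <= radius_mm**2)
    return field


def _affine(config: CohortConfig) -> np.ndarray:
    """Isotropic RAS affine with the world origin at the grid center."""
    vs = config.voxel_size_mm
    center = (np.array(config.shape, dtype=float) - 1) / 2.0
    aff = np.diag([vs, vs, vs, 1.0])
    aff[:3, 3] = -vs * center
    return aff


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one seeded cohort: volumes, subject table, truth mask.

    Patient (group B) baseline is scaled by the planted fractional effect
    before noise; every voxel carries linear age and TIV trends modulated by
    the baseline profile; volumes are smoothed at ``smooth_fwhm_mm`` after
    effect + noise, mirroring a preprocessing pipeline that smooths last.
    """
    rng = np.random.default_rng(config.seed)
    base = _baseline_template(config)
    effect = _effect_field(config)
    truth_mask = effect != 0
    profile = base / base.max()
    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])

    n_total = config.n_group_a + config.n_group_b
    groups = ["HC"] * config.n_group_a + ["PTSD"] * config.n_group_b
    ages = rng.uniform(*config.age_range, size=n_total)
    tivs = rng.normal(1400.0, 130.0, size=n_total)

    # Clinical scales: CAPS separates groups; cognition/depression matched.
    caps = np.where(
        np.array(groups) == "PTSD",
        np.clip(rng.normal(65.0, 15.0, n_total), 0, 136),
        np.clip(rng.normal(4.0, 3.0, n_total), 0, 136),
    )
    mmse = np.clip(rng.normal(28.5, 1.0, n_total), 0, 30)
    moca = np.clip(rng.normal(26.5, 1.8, n_total), 0, 30)
    gds = np.clip(rng.normal(2.0, 1.5, n_total), 0, 15)

    vols = np.empty((n_total,) + tuple(config.shape))
    effect_dev = np.zeros(n_total)
    for i, grp in enumerate(groups):
        v = base * (1.0 + effect) if grp == "PTSD" else base.copy()
        v = v + (
            config.age_slope * (ages[i] - age_mid)
            + config.tiv_slope * (tivs[i] - 1400.0)
        ) * profile
        noise = rng.normal(0.0, config.noise_sd, size=config.shape) if config.noise_sd else 0.0
        v = v + noise
        vols[i] = v
        if truth_mask.any() and config.noise_sd:
            effect_dev[i] = np.asarray(noise)[truth_mask].mean()

    if config.caps_coupling and config.noise_sd and truth_mask.any():
        dev = (effect_dev - effect_dev.mean()) / (effect_dev.std() or 1.0)
        caps = caps + config.caps_coupling * dev

    subject_ids = [f"sub-{i + 1:03d}" for i in range(n_total)]
    stack = VolumeStack(vols, _affine(config), subject_ids)
    if config.smooth_fwhm_mm > 0:
        stack = smooth_gaussian(stack, config.smooth_fwhm_mm)
    subjects = pd.DataFrame(
        {
            "id": subject_ids,
            "group": groups,
            "age": ages,
            "tiv": tivs,
            "caps": caps,
            "mmse": mmse,
            "moca": moca,
            "gds": gds,
        }
    )
    return SyntheticCohort(stack, subjects, truth_mask, config)


def simulate_expression(
    config: ExpressionConfig, regional_signal: np.ndarray
) -> ExpressionArray:
    """Generate a donor x region x gene array with planted spatial coupling.

    The first ``n_coupled`` genes share a cross-donor latent regional profile
    correlated with ``regional_signal`` at ``coupling_strength`` (plus
    per-donor noise), giving them both spatial association and high
    differential stability; the remaining genes are independent noise per
    donor (differential stability ~ 0).
    """
    signal = np.asarray(regional_signal, dtype=float)
    if signal.shape != (config.n_regions,):
        raise ValueError(
            f"regional_signal has length {signal.shape}, expected ({config.n_regions},)"
        )
    rng = np.random.default_rng(config.seed)
    # couple in rank space (van der Waerden normal scores): the achieved
    # Spearman correlation then tracks coupling_strength for any marginal
    # shape of the signal, including heavy-tailed t-profiles
    from scipy import stats as _stats

    if signal.std() > 0:
        scores = _stats.norm.ppf(
            _stats.rankdata(signal) / (config.n_regions + 1)
        )
        z = (scores - scores.mean()) / scores.std()
    else:
        z = np.zeros_like(signal)
    c = config.coupling_strength
    genes = [f"GENE{g + 1:05d}" for g in range(config.n_genes)]
    nd, nr, ng, nc = (
        config.n_donors, config.n_regions, config.n_genes, config.n_coupled,
    )
    values = np.empty((nd, nr, ng))
    if nc:
        # shared latent per coupled gene; per-donor measurement noise on top
        latents = c * z[:, None] + np.sqrt(
            max(0.0, 1.0 - c**2)
        ) * rng.standard_normal((nr, nc))
        values[:, :, :nc] = latents[None] + config.noise_sd * rng.standard_normal(
            (nd, nr, nc)
        )
    if ng > nc:
        values[:, :, nc:] = rng.standard_normal((nd, nr, ng - nc))
    return ExpressionArray(
        values=values,
        donors=[f"donor{d + 1}" for d in range(config.n_donors)],
        regions=list(range(1, config.n_regions + 1)),
        genes=genes,
        coupled_genes=genes[: config.n_coupled],
    )


def simulate_atlas(mask: np.ndarray, n_regions: int, seed: int = 0) -> np.ndarray:
    """Partition mask voxels into spatially compact labelled parcels.

    K-means on voxel coordinates (seeded, single init) yields a synthetic
    parcellation standing in for a labelled brain atlas: labels 1..n_regions
    inside the mask, 0 outside.
    """
    from sklearn.cluster import KMeans

    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if len(coords) < n_regions:
        raise ValueError(
            f"mask has {len(coords)} voxels; cannot form {n_regions} regions"
        )
    km = KMeans(n_clusters=n_regions, n_init=1, random_state=seed)
    labels = km.fit_predict(coords.astype(float))
    atlas = np.zeros(mask.shape, dtype=int)
    atlas[tuple(coords.T)] = labels + 1
    return atlas


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write one NIfTI per subject, subjects.tsv, truth mask and config.

    Round-trips losslessly through :func:`vicikit.io.read_cohort`.
    """
    from . import io as _io  # local import: io depends on vbm, not on us

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        for i, sid in enumerate(cohort.volumes.subject_ids):
            p = directory / f"{sid}_gmv.nii.gz"
            _io.write_volume(cohort.volumes.data[i], cohort.volumes.affine, p)
            paths[sid] = p
        paths["subjects"] = directory / "subjects.tsv"
        _io.write_table(cohort.subjects, paths["subjects"])
        paths["truth_mask"] = directory / "truth_mask.nii.gz"
        _io.write_volume(
            cohort.truth_mask.astype(np.uint8), cohort.volumes.affine, paths["truth_mask"]
        )
        paths["config"] = directory / "config.json"
        paths["config"].write_text(
            json.dumps(cohort.config.model_dump(), indent=2) + "\n"
        )
    except OSError as err:
        raise OSError(f"failed writing cohort under {directory}: {err}") from err
    return paths
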