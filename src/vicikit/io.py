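"""Format round-tripping: NIfTI-1 volumes and typed TSV tables.

All volumes go through nibabel as single-file .nii.gz with the affine
preserved bit-exact; tables are TSV (tab-separated, UTF-8, NaN for missing)
so locale decimal conventions never corrupt numeric columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthcohort import CohortConfig, ExpressionArray, SyntheticCohort
from .vbm import StatMap, VolumeStack

__all__ = [
    "read_volume",
    "write_volume",
    "read_volume_stack",
    "read_subjects",
    "write_table",
    "read_table",
    "write_statmap",
    "read_cohort",
    "read_expression",
    "write_expression",
    "read_gene_list",
]


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def read_volume_stack(paths: list[str | Path], subject_ids: list[str] | None = None) -> VolumeStack:
    """Load per-subject volumes; every file must share shape and affine."""
    if not paths:
        raise ValueError("no volume paths given")
    vols, affine = [], None
    for p in paths:
        data, aff = read_volume(p)
        if affine is None:
            affine, shape = aff, data.shape
        else:
            if data.shape != shape:
                raise ValueError(f"volume shape mismatch in {p}: {data.shape} != {shape}")
            if not np.array_equal(aff, affine):
                raise ValueError(f"affine mismatch in {p}")
        vols.append(data)
    if subject_ids is None:
        subject_ids = [Path(p).name.split(".")[0] for p in paths]
    return VolumeStack(np.stack(vols), affine, subject_ids)


def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", encoding="utf-8")


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read a subject table; clinical blanks parse as missing (NaN), not 0."""
    table = read_table(path)
    required = {"id", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"subject table {path} lacks column(s) {sorted(missing)}")
    return table


def write_statmap(statmap: StatMap, directory: str | Path, prefix: str = "stat") -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {
        "t": write_volume(statmap.t, statmap.affine, directory / f"{prefix}_t.nii.gz"),
        "p": write_volume(statmap.p_unc, statmap.affine, directory / f"{prefix}_p.nii.gz"),
        "mask": write_volume(
            statmap.mask.astype(np.uint8), statmap.affine, directory / f"{prefix}_mask.nii.gz"
        ),
    }
    (directory / f"{prefix}_meta.json").write_text(json.dumps({"df": statmap.df}) + "\n")
    return out


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`vicikit.synthcohort.write_cohort`."""
    directory = Path(directory)
    config = CohortConfig(**json.loads((directory / "config.json").read_text()))
    subjects = read_subjects(directory / "subjects.tsv")
    paths = [directory / f"{sid}_gmv.nii.gz" for sid in subjects["id"]]
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(f"missing volume for subject table row: {p}")
    stack = read_volume_stack(paths, subject_ids=list(subjects["id"]))
    truth, _ = read_volume(directory / "truth_mask.nii.gz")
    return SyntheticCohort(stack, subjects, truth.astype(bool), config)


def write_expression(arr: ExpressionArray, path: str | Path) -> Path:
    """Long-format TSV: donor, region, gene, value."""
    nd, nr, ng = arr.values.shape
    donors = np.repeat(arr.donors, nr * ng)
    regions = np.tile(np.repeat(arr.regions, ng), nd)
    genes = np.tile(arr.genes, nd * nr)
    return write_table(
        pd.DataFrame(
            {"donor": donors, "region": regions, "gene": genes,
             "value": arr.values.ravel()}
        ),
        path,
    )


def read_expression(path: str | Path) -> ExpressionArray:
    long = read_table(path)
    donors = list(pd.unique(long["donor"]))
    regions = [int(r) for r in pd.unique(long["region"])]
    genes = list(pd.unique(long["gene"]))
    cube = (
        long.set_index(["donor", "region", "gene"])["value"]
        .unstack(["region", "gene"])
        .loc[donors]
    )
    values = cube.to_numpy().reshape(len(donors), len(regions), len(genes))
    return ExpressionArray(values=values, donors=donors, regions=regions, genes=genes)


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text risk-gene list, one symbol per line; '#' comments allowed."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            out.append(sym)
    return out
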