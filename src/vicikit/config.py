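"""End-to-end pipeline configuration and deterministic seed fan-out."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .synthcohort import CohortConfig, ExpressionConfig

__all__ = ["PipelineConfig", "stage_seeds", "STAGES"]

# fixed stage order for seed fan-out; changing it would change every run
STAGES = ("cohort", "vbm", "split", "tune", "shapley", "permutation", "expression")


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Fan one master seed out to per-stage seeds.

    numpy SeedSequence(master).spawn(k) in the fixed STAGES order; each child
    contributes one 31-bit integer seed. Documented so that any two runs with
    the same master seed agree stage by stage.
    """
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


class PipelineConfig(BaseModel):
    """Every tunable threshold of the pipeline in one document.

    Defaults: voxel p < 0.001 with cluster-level FWE alpha 0.05, a 9:1
    train/test split with tenfold embedded CV, 1000 permutations, Bonferroni
    alpha 0.05, top-50% differential-stability filtering, 8 mm smoothing.
    Unknown keys are rejected on load.
    """

    model_config = ConfigDict(extra="forbid")

    voxel_p: float = Field(default=0.001, gt=0, lt=1)
    cluster_alpha: float = Field(default=0.05, gt=0, lt=1)
    test_fraction: float = Field(default=0.1, gt=0, lt=1)
    cv_folds: int = Field(default=10, ge=2)
    n_perm: int = Field(default=1000, ge=1)
    bonferroni_alpha: float = Field(default=0.05, gt=0, lt=1)
    ds_fraction: float = Field(default=0.5, gt=0, le=1)
    smooth_fwhm: float = Field(default=8.0, ge=0)
    feature_mode: str = Field(default="paper", pattern="^(paper|safe)$")
    vici_scheme: str = Field(default="unit", pattern="^(unit|importance)$")
    seed: int = 0
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    expression: ExpressionConfig = Field(default_factory=ExpressionConfig)

    def seeds(self) -> dict[str, int]:
        return stage_seeds(self.seed)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        doc = self.model_dump()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls(**doc)
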