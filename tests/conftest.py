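"""Shared fixtures: small seeded cohorts and derived analysis objects.

Everything is generated at test time; session scope keeps the expensive
planted-effect cohort and its permutation-FWE analysis shared across test
modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from vicikit import classify
from vicikit.synthcohort import CohortConfig, simulate_cohort
from vicikit.vbm import DesignSpec, cluster_fwe, significant_mask

# one 16 mm sphere fits a 60x72x60 mm grid with room for smoothing spill
SMALL_SHAPE = (20, 24, 20)
SMALL_CLUSTER = ((10, 12, 10), 16.0, -0.15)


def make_cohort(seed: int = 11, **overrides) -> "SyntheticCohort":  # noqa: F821
    params = dict(
        n_group_a=20,
        n_group_b=31,
        shape=SMALL_SHAPE,
        effect_clusters=[SMALL_CLUSTER],
        noise_sd=0.02,
        seed=seed,
    )
    params.update(overrides)
    return simulate_cohort(CohortConfig(**params))


@pytest.fixture(scope="session")
def design() -> DesignSpec:
    return DesignSpec()


@pytest.fixture(scope="session")
def planted_cohort():
    return make_cohort()


@pytest.fixture(scope="session")
def planted_fwe(planted_cohort, design):
    return cluster_fwe(
        planted_cohort.volumes, planted_cohort.subjects, design, n_perm=99, seed=3
    )


@pytest.fixture(scope="session")
def planted_features(planted_cohort, planted_fwe, design):
    mask = significant_mask(planted_fwe, alpha=0.05)
    return classify.extract_features(
        planted_cohort.volumes, mask, planted_cohort.subjects, design
    )


@pytest.fixture()
def toy_subjects() -> pd.DataFrame:
    rng = np.random.default_rng(5)
    n = 12
    return pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(n)],
            "group": ["HC"] * 6 + ["PTSD"] * 6,
            "age": rng.uniform(60, 80, n),
            "tiv": rng.normal(1400, 100, n),
            "caps": rng.normal(30, 20, n),
            "mmse": rng.normal(28, 1, n),
            "moca": rng.normal(26, 2, n),
            "gds": rng.normal(2, 1, n),
        }
    )
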