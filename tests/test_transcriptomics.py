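"""Regional aggregation, SRS normalization, DS filtering, gene association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vicikit.synthcohort import ExpressionArray, ExpressionConfig, simulate_expression
from vicikit.transcriptomics import (
    differential_stability,
    gene_vici_association,
    normalize_expression,
    regional_aggregate,
    select_stable_genes,
)
from vicikit.vbm import StatMap


def _statmap(t, mask=None):
    mask = np.ones(t.shape, bool) if mask is None else mask
    return StatMap(t=t, p_unc=np.ones(t.shape), df=10, mask=mask, affine=np.eye(4))


def _arr(values, genes=None, regions=None):
    values = np.asarray(values, float)
    nd, nr, ng = values.shape
    return ExpressionArray(
        values=values,
        donors=[f"d{i}" for i in range(nd)],
        regions=regions or list(range(1, nr + 1)),
        genes=genes or [f"g{i}" for i in range(ng)],
    )


class TestRegionalAggregate:
    def test_uniform_map(self):
        atlas = np.zeros((4, 4, 4), int)
        atlas[:2] = 1
        atlas[2:] = 2
        out = regional_aggregate(_statmap(np.full((4, 4, 4), 2.0)), atlas)
        assert out.tolist() == [2.0, 2.0]

    def test_single_region_equals_global_masked_mean(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(3, 3, 3))
        mask = rng.random((3, 3, 3)) > 0.4
        atlas = np.ones((3, 3, 3), int)
        out = regional_aggregate(_statmap(t, mask), atlas)
        assert out[1] == pytest.approx(t[mask].mean())

    def test_printed_three_region_atlas(self):
        # region 1 holds t {1, 3}; region 2 holds {2}; region 3 holds {-4}
        t = np.array([1.0, 3.0, 2.0, -4.0]).reshape(4, 1, 1)
        atlas = np.array([1, 1, 2, 3]).reshape(4, 1, 1)
        out = regional_aggregate(_statmap(t), atlas)
        assert out.tolist() == [2.0, 2.0, -4.0]

    def test_uncovered_region_is_missing(self):
        t = np.zeros((2, 1, 1))
        mask = np.array([True, False]).reshape(2, 1, 1)
        atlas = np.array([1, 2]).reshape(2, 1, 1)
        out = regional_aggregate(_statmap(t, mask), atlas)
        assert np.isnan(out[2]) and not np.isnan(out[1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regional_aggregate(_statmap(np.zeros((2, 2, 2))), np.zeros((3, 3, 3), int))


class TestNormalizeExpression:
    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(1)
        arr = _arr(rng.normal(size=(3, 12, 20)) * 5 + 7)
        out = normalize_expression(arr)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0

    def test_constant_gene_flagged(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(2, 6, 3))
        values[:, :, 1] = 4.2  # identical across regions
        out = normalize_expression(_arr(values))
        assert "g1" in out.rank_fallback
        assert np.allclose(out.values[:, :, 1], 0.5)

    @staticmethod
    def _srs_oracle(x):
        med = np.median(x)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        s = 1 / (1 + np.exp(-(x - med) / (iqr / 1.35)))
        return (s - s.min()) / (s.max() - s.min())

    def test_each_pass_preserves_ranks_of_its_input(self):
        # The sigmoid is monotone, so the final cross-region ranks per gene
        # equal the ranks of the first-pass output (recomputed independently).
        rng = np.random.default_rng(3)
        values = rng.normal(size=(2, 8, 5))
        out = normalize_expression(_arr(values))
        for d in range(2):
            stage = np.stack([self._srs_oracle(values[d, r]) for r in range(8)])
            for g in range(5):
                np.testing.assert_array_equal(
                    stats.rankdata(out.values[d, :, g]),
                    stats.rankdata(stage[:, g]),
                )
            # and pass 1 preserves within-region cross-gene ranks of the input
            for r in range(8):
                np.testing.assert_array_equal(
                    stats.rankdata(stage[r]), stats.rankdata(values[d, r])
                )

    def test_matches_independent_sigmoid_oracle(self):
        # 3-region, 3-gene printed toy matrix, one donor
        values = np.array(
            [[[1.0, 10.0, 5.0], [30.0, 2.0, 7.0], [4.0, 20.0, 3.0]]]
        )
        out = normalize_expression(_arr(values))
        stage = np.stack([self._srs_oracle(values[0, r]) for r in range(3)])
        expected = np.stack(
            [self._srs_oracle(stage[:, g]) for g in range(3)], axis=1
        )
        np.testing.assert_allclose(out.values[0], expected, atol=1e-12)

    def test_single_region_rejected(self):
        with pytest.raises(ValueError):
            normalize_expression(_arr(np.zeros((2, 1, 3))))


class TestDifferentialStability:
    def test_identical_donors_give_ds_one(self):
        rng = np.random.default_rng(4)
        profile = rng.normal(size=(10, 6))
        arr = _arr(np.stack([profile, profile]))
        ds = differential_stability(arr)
        np.testing.assert_allclose(ds.to_numpy(), 1.0, atol=1e-12)

    def test_independent_donors_centered_at_zero(self):
        rng = np.random.default_rng(5)
        arr = _arr(rng.normal(size=(4, 50, 200)))
        ds = differential_stability(arr)
        assert abs(ds.mean()) < 0.05

    def test_single_donor_rejected(self):
        with pytest.raises(ValueError):
            differential_stability(_arr(np.zeros((1, 5, 3))))

    def test_invariant_to_monotone_per_donor_transforms(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(3, 20, 4))
        ds_a = differential_stability(_arr(values))
        warped = values.copy()
        warped[0] = np.exp(warped[0])
        warped[1] = warped[1] ** 3
        warped[2] = 2 * warped[2] - 7
        ds_b = differential_stability(_arr(warped))
        np.testing.assert_allclose(ds_a.to_numpy(), ds_b.to_numpy(), atol=1e-12)

    def test_top_fraction_selection_with_name_tiebreak(self):
        ds = pd.Series(
            [0.9, 0.5, 0.5, 0.1], index=pd.Index(["gb", "gc", "ga", "gd"], name="gene")
        )
        assert select_stable_genes(ds, 0.5) == ["gb", "ga"]
        assert select_stable_genes(ds, 1.0) == ["gb", "ga", "gc", "gd"]


class TestGeneAssociation:
    def test_expression_equal_to_t_gives_rho_one(self):
        t = pd.Series(np.arange(10.0), index=pd.RangeIndex(1, 11, name="region"))
        values = np.tile(np.arange(10.0)[None, :, None], (2, 1, 3))
        arr = _arr(values)
        out = gene_vici_association(t, arr, ["g0"])
        assert out.iloc[0]["rho"] == pytest.approx(1.0)
        assert out.iloc[0]["significant"]

    def test_missing_risk_gene_reported(self):
        t = pd.Series(np.arange(8.0), index=pd.RangeIndex(1, 9, name="region"))
        arr = _arr(np.random.default_rng(7).normal(size=(2, 8, 2)))
        out = gene_vici_association(t, arr, ["g0", "NOT_THERE"])
        row = out[out["gene"] == "NOT_THERE"].iloc[0]
        assert not row["present"] and np.isnan(row["rho"])

    def test_bonferroni_uses_tested_gene_count(self):
        rng = np.random.default_rng(8)
        t = pd.Series(rng.normal(size=20), index=pd.RangeIndex(1, 21, name="region"))
        arr = _arr(rng.normal(size=(2, 20, 6)))
        risk = [f"g{i}" for i in range(5)] + ["ABSENT"]
        out = gene_vici_association(t, arr, risk)
        present = out[out["present"]]
        np.testing.assert_allclose(
            present["p_bonf"], np.minimum(1.0, present["p"] * 5), atol=1e-12
        )

    def test_too_few_common_regions_rejected(self):
        t = pd.Series([1.0, 2.0, 3.0], index=pd.RangeIndex(1, 4, name="region"))
        arr = _arr(np.zeros((2, 3, 2)))
        with pytest.raises(ValueError, match=">= 4"):
            gene_vici_association(t, arr, ["g0"])

    def test_null_family_wise_error_controlled(self):
        """Over null replicates, any-false-positive rate after Bonferroni
        stays at or below alpha (binomial CI)."""
        rng = np.random.default_rng(9)
        hits = 0
        reps = 200
        for _ in range(reps):
            t = pd.Series(
                rng.normal(size=30), index=pd.RangeIndex(1, 31, name="region")
            )
            arr = _arr(rng.normal(size=(2, 30, 10)))
            out = gene_vici_association(t, arr, list(arr.genes))
            hits += bool(out["significant"].any())
        # alpha=0.05: 95% binomial upper bound at p=0.05, n=200 is ~0.09
        assert hits / reps <= 0.09

    def test_pipeline_invariant_to_region_relabeling(self):
        rng = np.random.default_rng(10)
        t_vals = rng.normal(size=12)
        values = rng.normal(size=(2, 12, 4))
        regions = list(range(1, 13))
        t = pd.Series(t_vals, index=pd.Index(regions, name="region"))
        out_a = gene_vici_association(t, _arr(values, regions=regions), ["g0", "g1"])
        # permute region ids consistently in both inputs
        perm = rng.permutation(12)
        new_ids = [regions[i] for i in perm]
        t_b = pd.Series(t_vals, index=pd.Index(new_ids, name="region"))
        out_b = gene_vici_association(
            t_b, _arr(values, regions=new_ids), ["g0", "g1"]
        )
        np.testing.assert_allclose(out_a["rho"], out_b["rho"], atol=1e-12)


class TestPlantedRecoveryUnit:
    def test_coupled_genes_have_high_ds_and_association(self):
        rng = np.random.default_rng(11)
        signal = rng.normal(size=60)
        # gene count kept microarray-like: a small array would let the few
        # coupled genes bias the across-gene normalization pass
        cfg = ExpressionConfig(
            n_donors=4, n_regions=60, n_genes=1000, n_coupled=5, n_risk=20,
            coupling_strength=0.9, noise_sd=0.3, seed=12,
        )
        arr = simulate_expression(cfg, signal)
        norm = normalize_expression(arr)
        ds = differential_stability(norm)
        assert ds[arr.coupled_genes].min() > ds.drop(arr.coupled_genes).mean() + 0.3
        t = pd.Series(signal, index=pd.Index(arr.regions, name="region"))
        out = gene_vici_association(t, norm, arr.genes[:20])
        sig = set(out[out["significant"]]["gene"])
        assert sig == set(arr.coupled_genes)
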