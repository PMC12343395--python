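"""Feature extraction, splitting, tuning, metrics and permutation tests."""

import numpy as np
import pytest

from vicikit import classify
from vicikit.classify import (
    ClassifierSpec,
    FeatureMatrix,
    benchmark,
    evaluate,
    extract_features,
    permutation_significance,
    split_train_test,
    tune_fit,
)
from vicikit.vbm import DesignSpec, fit_glm_tmap

from conftest import make_cohort


def _toy_fm(n=40, d=8, separation=0.0, seed=0) -> FeatureMatrix:
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    X = rng.normal(size=(n, d)) + separation * y[:, None]
    return FeatureMatrix(X, y, np.zeros((d, 3), int), [f"s{i}" for i in range(n)])


class TestExtractFeatures:
    def test_shape_contract(self, planted_cohort, design):
        mask = np.zeros(planted_cohort.volumes.shape, bool)
        mask.ravel()[:10] = True
        fm = extract_features(planted_cohort.volumes, mask, planted_cohort.subjects, design)
        assert fm.X.shape == (51, 10)
        assert len(fm.feature_index) == 10

    def test_back_projection_recovers_voxel_coordinates(self, planted_cohort, design):
        rng = np.random.default_rng(4)
        mask = np.zeros(planted_cohort.volumes.shape, bool)
        chosen = rng.choice(mask.size, 25, replace=False)
        mask.ravel()[chosen] = True
        fm = extract_features(planted_cohort.volumes, mask, planted_cohort.subjects, design)
        for j, ijk in enumerate(fm.feature_index):
            assert fm.X[:, j] == pytest.approx(
                planted_cohort.volumes.data[:, ijk[0], ijk[1], ijk[2]]
            )
        # ordering is by linear voxel index
        lin = np.ravel_multi_index(fm.feature_index.T, planted_cohort.volumes.shape)
        assert (np.diff(lin) > 0).all()

    def test_truth_mask_features_reduced_in_patients(self, planted_cohort, design):
        fm = extract_features(
            planted_cohort.volumes, planted_cohort.truth_mask,
            planted_cohort.subjects, design,
        )
        patients = fm.y == 1
        # per-column oracle: group means differ in the planted direction
        diff = fm.X[patients].mean(axis=0) - fm.X[~patients].mean(axis=0)
        assert (diff < 0).mean() > 0.95

    def test_empty_mask_rejected(self, planted_cohort, design):
        mask = np.zeros(planted_cohort.volumes.shape, bool)
        with pytest.raises(ValueError, match="empty"):
            extract_features(planted_cohort.volumes, mask, planted_cohort.subjects, design)


class TestSplit:
    def test_nine_to_one_ratio(self):
        fm = _toy_fm(n=100)
        train, test, _, _ = split_train_test(fm, 0.1, seed=0)
        assert len(train.y) == 90
        assert len(test.y) == 10
        assert test.y.sum() == 5  # stratified

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(_toy_fm(), 0.0)

    def test_same_seed_reproduces_indices(self):
        fm = _toy_fm(n=60)
        _, _, tr1, te1 = split_train_test(fm, 0.1, seed=9)
        _, _, tr2, te2 = split_train_test(fm, 0.1, seed=9)
        assert np.array_equal(tr1, tr2) and np.array_equal(te1, te2)

    def test_partitions_disjoint_and_exhaustive(self):
        fm = _toy_fm(n=53)
        _, _, tr, te = split_train_test(fm, 0.1, seed=2)
        assert len(set(tr) & set(te)) == 0
        assert len(set(tr) | set(te)) == 53


class TestTuneFit:
    def test_single_configuration_grid(self):
        fm = _toy_fm(n=40, separation=2.0)
        spec = ClassifierSpec("logistic", {"clf__C": [1.0]}, seed=0)
        res = tune_fit(spec, fm)
        assert len(res.cv_table) == 1
        assert res.n_folds == 10
        # model equals a direct fit of the same configuration
        direct = classify._make_estimator(spec).set_params(clf__C=1.0)
        direct.fit(fm.X, fm.y)
        np.testing.assert_allclose(
            classify.predict_scores(res.model, fm.X),
            classify.predict_scores(direct, fm.X),
            atol=1e-12,
        )

    def test_separable_data_reaches_cv_auc_one(self):
        fm = _toy_fm(n=40, separation=6.0)
        res = tune_fit(ClassifierSpec("svm_linear", {"clf__C": [1.0]}, 0), fm)
        assert res.cv_table["mean_auc"].max() == pytest.approx(1.0)

    def test_fold_count_lowered_with_warning(self):
        fm = _toy_fm(n=12)
        with pytest.warns(UserWarning, match="lowering CV folds"):
            res = tune_fit(ClassifierSpec("logistic", {"clf__C": [1.0]}, 0), fm)
        assert res.n_folds == 6

    def test_grid_selection_reproducible(self):
        fm = _toy_fm(n=40, separation=1.0, seed=3)
        spec = ClassifierSpec("svm_linear", {"clf__C": [0.1, 1.0, 10.0]}, seed=5)
        r1, r2 = tune_fit(spec, fm), tune_fit(spec, fm)
        assert r1.best_params == r2.best_params
        assert r1.cv_table["mean_auc"].tolist() == r2.cv_table["mean_auc"].tolist()


class TestEvaluate:
    class _Fixed:
        """Stub model with printed predictions and scores."""

        def __init__(self, preds, scores):
            self.preds, self.scores = np.asarray(preds), np.asarray(scores)

        def predict(self, X):
            return self.preds

        def predict_proba(self, X):
            return np.c_[1 - self.scores, self.scores]

    def test_printed_example_with_pair_counting_oracle(self):
        y = np.array([1, 0, 0, 1])
        scores = np.array([0.9, 0.8, 0.2, 0.6])
        fm = FeatureMatrix(np.zeros((4, 1)), y, np.zeros((1, 3), int), list("abcd"))
        rep = evaluate(self._Fixed([1, 1, 0, 0], scores), fm)
        assert rep.accuracy == 0.5
        assert rep.sensitivity == 0.5
        assert rep.specificity == 0.5
        # exhaustive Mann-Whitney pair count
        pos, neg = scores[y == 1], scores[y == 0]
        pairs = [(0.5 if p == q else float(p > q)) for p in pos for q in neg]
        assert rep.roc_auc == pytest.approx(np.mean(pairs)) == pytest.approx(0.75)

    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        fm = FeatureMatrix(np.zeros((4, 1)), y, np.zeros((1, 3), int), list("abcd"))
        rep = evaluate(self._Fixed(y, np.array([0.1, 0.2, 0.8, 0.9])), fm)
        assert (rep.accuracy, rep.sensitivity, rep.specificity, rep.roc_auc) == (1, 1, 1, 1)

    def test_label_inversion_swaps_sensitivity_specificity(self):
        y = np.array([1, 0, 0, 1, 0])
        preds = np.array([1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.7, 0.3, 0.4, 0.2])
        fm = FeatureMatrix(np.zeros((5, 1)), y, np.zeros((1, 3), int), list("abcde"))
        rep = evaluate(self._Fixed(preds, scores), fm)
        fm_inv = FeatureMatrix(np.zeros((5, 1)), 1 - y, np.zeros((1, 3), int), list("abcde"))
        rep_inv = evaluate(self._Fixed(1 - preds, 1 - scores), fm_inv)
        assert rep.sensitivity == rep_inv.specificity
        assert rep.specificity == rep_inv.sensitivity

    def test_single_class_test_flags_auc_undefined(self):
        y = np.ones(3, int)
        fm = FeatureMatrix(np.zeros((3, 1)), y, np.zeros((1, 3), int), list("abc"))
        rep = evaluate(self._Fixed(y, np.array([0.9, 0.8, 0.7])), fm)
        assert rep.auc_undefined and rep.roc_auc is None


class TestPermutationSignificance:
    def test_add_one_estimator_lower_bound(self):
        fm = _toy_fm(n=40, separation=6.0, seed=1)
        spec = ClassifierSpec("logistic", {"clf__C": [1.0]}, 0)
        res = permutation_significance(spec, fm, n_perm=99, seed=2)
        assert res.p == pytest.approx(1 / 100)
        assert res.observed_auc == 1.0

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_significance(
                ClassifierSpec("logistic", {"clf__C": [1.0]}, 0), _toy_fm(), n_perm=0
            )

    def test_deterministic(self):
        fm = _toy_fm(n=30, separation=1.0)
        spec = ClassifierSpec("logistic", {"clf__C": [1.0]}, 0)
        r1 = permutation_significance(spec, fm, n_perm=19, seed=4, n_splits=2)
        r2 = permutation_significance(spec, fm, n_perm=19, seed=4, n_splits=2)
        assert r1.p == r2.p
        assert np.array_equal(r1.null_aucs, r2.null_aucs)


@pytest.fixture(scope="module")
def small_features(planted_features):
    # a 200-voxel subset keeps the tree/boosting fits quick
    return FeatureMatrix(
        planted_features.X[:, :200],
        planted_features.y,
        planted_features.feature_index[:200],
        planted_features.subject_ids,
    )


class TestBenchmark:
    def test_six_families_schema_and_order(self, small_features):
        table = benchmark(small_features, seed=1)
        assert len(table) == 6
        assert {"family", "accuracy", "sensitivity", "specificity", "roc_auc"} <= set(
            table.columns
        )
        acc = table["accuracy"].to_numpy()
        assert (np.diff(acc) <= 1e-12).all()  # sorted descending

    def test_rerun_identical(self, small_features):
        t1 = benchmark(small_features, seed=1)
        t2 = benchmark(small_features, seed=1)
        assert t1.drop(columns=["best_params"]).equals(t2.drop(columns=["best_params"]))

    def test_single_spec_equals_direct_evaluate(self):
        fm = _toy_fm(n=40, separation=2.0)
        spec = ClassifierSpec("logistic", {"clf__C": [1.0]}, 0)
        table = benchmark(fm, [spec], seed=7)
        train, test, _, _ = split_train_test(fm, 0.1, seed=7)
        rep = evaluate(tune_fit(spec, train).model, test)
        assert table.iloc[0]["accuracy"] == rep.accuracy
        assert table.iloc[0]["roc_auc"] == rep.roc_auc


class TestSelectionCircularity:
    def test_paper_mode_optimistic_on_null_data(self, design):
        """Selecting features on all subjects before splitting inflates
        held-out AUC relative to training-only selection on null cohorts."""
        spec = ClassifierSpec("logistic", {"clf__C": [1.0]}, 0)
        paper_aucs, safe_aucs = [], []
        for seed in range(8):
            cohort = make_cohort(
                n_group_a=15, n_group_b=15, shape=(10, 12, 10),
                effect_clusters=[], noise_sd=0.05, smooth_fwhm_mm=0.0,
                seed=100 + seed,
            )
            y = (cohort.subjects["group"] == "PTSD").to_numpy(int)
            rng = np.random.default_rng(seed)
            idx = np.arange(30)
            from sklearn.model_selection import train_test_split

            tr, te = train_test_split(idx, test_size=0.2, stratify=y, random_state=seed)
            for mode, aucs in (("paper", paper_aucs), ("safe", safe_aucs)):
                sel = idx if mode == "paper" else tr
                sub_stack = type(cohort.volumes)(
                    cohort.volumes.data[sel], cohort.volumes.affine,
                    [cohort.volumes.subject_ids[i] for i in sel],
                )
                sm = fit_glm_tmap(
                    sub_stack, cohort.subjects.iloc[sel].reset_index(drop=True), design
                )
                # top-30 most significant voxels as features
                flat_p = np.where(sm.mask, sm.p_unc, 1.0).ravel()
                mask = np.zeros(flat_p.size, bool)
                mask[np.argsort(flat_p)[:30]] = True
                fm = extract_features(
                    cohort.volumes, mask.reshape(cohort.volumes.shape),
                    cohort.subjects, design,
                )
                model = tune_fit(spec, fm.subset(tr), cv_folds=5).model
                rep = evaluate(model, fm.subset(te))
                aucs.append(rep.roc_auc)
        assert np.mean(paper_aucs) > np.mean(safe_aucs) + 0.1
        assert abs(np.mean(safe_aucs) - 0.5) < 0.15
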