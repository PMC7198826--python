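import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.base import clone

from dynconn.classify import (
    FEATURE_TYPES,
    HyperGrid,
    MultiLevelFCClassifier,
    compute_metrics,
    extract_feature_tables,
    fuse_scores,
    nested_cv,
    selection_frequency,
    train_linear_svm,
)
from dynconn.errors import DimensionError, MetricsWarning


class TestLinearSVM:
    def test_separable_data_fits_perfectly(self, rng):
        y = np.array([1] * 15 + [-1] * 15)
        x = rng.normal(0, 0.1, size=(30, 1)) + 10.0 * y.reshape(-1, 1)
        model = train_linear_svm(x, y, tradeoff=1.0)
        assert (model.predict(x) == y).all()

    def test_label_flip_negates_scores(self, rng):
        y = np.array([1] * 10 + [-1] * 10)
        x = rng.standard_normal((20, 3)) + 0.5 * y.reshape(-1, 1)
        s1 = train_linear_svm(x, y, 2.0, tol=1e-8).decision_function(x)
        s2 = train_linear_svm(x, -y, 2.0, tol=1e-8).decision_function(x)
        np.testing.assert_allclose(s1, -s2, atol=1e-6)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_linear_svm(rng.standard_normal((5, 2)), np.ones(5))

    def test_agrees_with_dual_qp_oracle(self):
        """Training-point decision signs match an independent quadratic-program
        solution of the soft-margin dual on a 10-point toy set."""
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(-1, 0.6, (5, 2)), rng.normal(1, 0.6, (5, 2))])
        y = np.array([-1.0] * 5 + [1.0] * 5)
        c = 1.0
        gram = (x @ x.T) * np.outer(y, y)

        def neg_dual(a):
            return 0.5 * a @ gram @ a - a.sum()

        res = minimize(
            neg_dual,
            x0=np.full(10, 0.1),
            bounds=[(0, c)] * 10,
            constraints={"type": "eq", "fun": lambda a: a @ y},
            method="SLSQP",
            options={"ftol": 1e-12, "maxiter": 500},
        )
        a = res.x
        w = (a * y) @ x
        sv = (a > 1e-6) & (a < c - 1e-6)
        b = np.mean(y[sv] - x[sv] @ w)
        oracle_scores = x @ w + b
        model = train_linear_svm(x, y, c)
        np.testing.assert_allclose(
            model.decision_function(x), oracle_scores, atol=1e-4
        )


class TestFusion:
    def test_single_nonzero_weight_returns_that_score(self):
        assert fuse_scores([0.7, -0.2, 0.1], [1, 0, 0]) == pytest.approx(0.7)

    def test_exact_tie_predicts_control(self):
        fused = fuse_scores([1.0, -1.0, 0.0], [1, 1, 1])
        assert fused == 0.0
        assert np.where(fused > 0, 1, -1) == -1

    def test_normalization(self):
        assert fuse_scores([1.0, 1.0, 1.0], [0.2, 0.3, 0.5]) == pytest.approx(1.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            fuse_scores([1.0, 2.0, 3.0], [0, 0, 0])


class TestMetrics:
    def test_perfect_classifier(self):
        y = np.array([1, -1, 1, -1])
        m = compute_metrics(y, y)
        for v in (m.acc, m.tpr, m.tnr, m.ppv, m.npv, m.f1):
            assert v == 1.0

    def test_hand_computed_confusion(self):
        true = np.array([1] * 5 + [-1] * 5)
        pred = np.array([1, 1, 1, -1, -1, -1, -1, -1, -1, 1])
        m = compute_metrics(pred, true)
        assert (m.tp, m.tn, m.fp, m.fn) == (3, 4, 1, 2)
        assert m.acc == pytest.approx(0.7)
        assert m.tpr == pytest.approx(0.6)
        assert m.tnr == pytest.approx(0.8)
        assert m.ppv == pytest.approx(0.75)
        assert m.npv == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)

    def test_degenerate_class_gives_nan_with_warning(self):
        with pytest.warns(MetricsWarning):
            m = compute_metrics(np.array([-1, -1]), np.array([-1, -1]))
        assert m.acc == 1.0
        assert np.isnan(m.tpr)

    def test_identity_system_on_random_confusions(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = rng.integers(1, 30, size=4)
            true = np.array([1] * (tp + fn) + [-1] * (tn + fp))
            pred = np.concatenate(
                [np.ones(tp), -np.ones(fn), -np.ones(tn), np.ones(fp)]
            ).astype(int)
            m = compute_metrics(pred, true)
            p, n = tp + fn, tn + fp
            assert m.acc == pytest.approx((m.tpr * p + m.tnr * n) / (p + n))
            assert m.f1 == pytest.approx(2 * m.ppv * m.tpr / (m.ppv + m.tpr))

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            compute_metrics(np.array([1]), np.array([1, -1]))


@pytest.fixture(scope="module")
def tiny_kwargs():
    return dict(
        lo_window=40, lo_step=8, lo_order=2, ho_window=30, ho_step=10, ho_order=2
    )


class TestEstimator:
    def test_sklearn_params_contract(self):
        clf = MultiLevelFCClassifier(lo_window=50, lam=0.2)
        cloned = clone(clf)
        assert cloned.get_params()["lo_window"] == 50
        assert cloned.set_params(lam=0.4).lam == 0.4

    def test_fit_predict_shapes_and_classes(self, tiny_cohort, tiny_kwargs):
        cohort, _ = tiny_cohort
        clf = MultiLevelFCClassifier(**tiny_kwargs).fit(
            cohort.data_list(), cohort.labels()
        )
        assert (clf.classes_ == [-1, 1]).all()
        pred = clf.predict(cohort.data_list())
        assert set(np.unique(pred)) <= {-1, 1}
        assert pred.shape == (len(cohort),)

    def test_single_alpha_reproduces_single_classifier(self, tiny_cohort, tiny_kwargs):
        """Fusing with one nonzero weight is exactly the corresponding
        single-network classifier (the degenerate-fusion case)."""
        cohort, _ = tiny_cohort
        x, y = cohort.data_list(), cohort.labels()
        for t, alphas in zip(FEATURE_TYPES, ((1, 0, 0), (0, 1, 0), (0, 0, 1))):
            clf = MultiLevelFCClassifier(alphas=alphas, **tiny_kwargs).fit(x, y)
            tables = clf._extract(x)
            single = clf.models_[t].decision_scores(tables[t])
            np.testing.assert_allclose(clf.decision_function(x), single, atol=1e-12)

    def test_labels_validated(self, tiny_cohort, tiny_kwargs):
        cohort, _ = tiny_cohort
        with pytest.raises(ValueError):
            MultiLevelFCClassifier(**tiny_kwargs).fit(
                cohort.data_list(), np.zeros(len(cohort))
            )


@pytest.fixture(scope="module")
def cv_result(tiny_cohort):
    cohort, _ = tiny_cohort
    grid = HyperGrid(
        p_thresholds=(0.05, 0.1),
        lambdas=(0.1, 0.3),
        svm_tradeoffs=(0.5, 2.0),
        fusion_weights=(0.2, 0.5, 0.8),
    )
    return nested_cv(
        cohort,
        grid=grid,
        outer_folds=4,
        inner_folds=3,
        repetitions=2,
        seed=0,
        lo_window=40,
        lo_step=8,
        lo_order=2,
        ho_window=30,
        ho_step=10,
        ho_order=2,
    )


class TestNestedCV:
    def test_folds_partition_each_repetition(self, cv_result, tiny_cohort):
        cohort, _ = tiny_cohort
        y = cohort.labels()
        for rep in range(cv_result.repetitions):
            test_idx = np.concatenate(
                [f.test_indices for f in cv_result.folds if f.repetition == rep]
            )
            assert sorted(test_idx.tolist()) == list(range(len(cohort)))
            for f in cv_result.folds:
                if f.repetition != rep:
                    continue
                n_pos = (y[f.test_indices] == 1).sum()
                n_neg = (y[f.test_indices] == -1).sum()
                assert abs(n_pos - 10 / 4) <= 1 and abs(n_neg - 10 / 4) <= 1

    def test_tuned_parameters_come_from_the_grid(self, cv_result):
        for f in cv_result.folds:
            for t, (p, lam, c) in f.tuned_params.items():
                assert p in (0.05, 0.1)
                assert lam in (0.1, 0.3)
                assert c in (0.5, 2.0)
            assert sum(f.alphas.values()) == pytest.approx(1.0)

    def test_aggregate_over_repetitions(self, cv_result):
        accs = [m.acc for m in cv_result.metrics_per_rep]
        assert cv_result.aggregate["ACC"]["mean"] == pytest.approx(np.mean(accs))
        assert cv_result.aggregate["ACC"]["sd"] == pytest.approx(np.std(accs))

    def test_selection_frequency_bounds_and_order(self, cv_result):
        freq = selection_frequency(cv_result)
        max_count = cv_result.outer_folds * cv_result.repetitions
        assert (freq["count"] <= max_count).all()
        assert (freq["count"] >= 1).all()
        for _, block in freq.groupby("feature_type"):
            assert (np.diff(block["count"].to_numpy()) <= 0).all()
        assert (freq["roi_i"] > freq["roi_j"]).all()

    def test_too_small_cohort_names_stratification(self, tiny_cohort):
        cohort, _ = tiny_cohort
        with pytest.raises(ValueError, match="stratified"):
            nested_cv(
                cohort.data_list()[:8],
                cohort.labels()[:8],
                outer_folds=6,
                lo_window=40,
                ho_window=30,
            )


def test_feature_tables_are_per_subject(tiny_cohort):
    """Feature extraction depends only on a subject's own series, so tables
    computed on a sub-cohort equal the corresponding rows of the full table."""
    cohort, _ = tiny_cohort
    kw = dict(lo_window=40, lo_step=8, lo_order=2, ho_window=30, ho_step=10, ho_order=2)
    full = extract_feature_tables(cohort.data_list(), **kw)
    part = extract_feature_tables(cohort.data_list()[:5], **kw)
    for t in FEATURE_TYPES:
        np.testing.assert_array_equal(full[t][:5], part[t])
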