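"""Linear SVM: solver correctness, consistent-set CV, AUC, weight scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promsig.features import FeatureMatrix, FeatureVector
from promsig.svm import (
    TrainConfig,
    auc,
    build_consistent_positive_set,
    class_weight,
    decision_score,
    double_loop_cv,
    estimate_C,
    is_reliable,
    scale_weights,
    train,
)


def make_matrix(X, y, promoters=None):
    rows = []
    for i, (x, lab) in enumerate(zip(X, y)):
        genes = frozenset({promoters[i]}) if promoters else frozenset()
        rows.append(FeatureVector(f"e{i}", np.asarray(x), genes, int(lab)))
    return FeatureMatrix(rows, [f"m{j}" for j in range(len(X[0]))])


class TestEstimateC:
    def test_norm_four_rows(self):
        X = np.array([[2.0, 0.0], [0.0, 2.0]])
        assert estimate_C(X) == pytest.approx(0.25)

    def test_unit_norm_rows(self):
        assert estimate_C(np.eye(3)) == pytest.approx(1.0)

    def test_homogeneity_scaling_rows_by_two_divides_by_four(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(1.0, (20, 5)).astype(float) + 0.1
        assert estimate_C(2 * X) == pytest.approx(estimate_C(X) / 4)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            estimate_C(np.zeros((3, 2)))


class TestTrain:
    def test_analytic_1d_separable(self):
        model = train(np.array([[-1.0], [1.0]]), np.array([-1, 1]), C=100.0, w1=1.0)
        assert model.w[0] == pytest.approx(1.0, abs=1e-4)
        assert model.b == pytest.approx(0.0, abs=1e-4)

    def test_label_flip_negates_solution(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=40) > 0, 1, -1)
        m1 = train(X, y, C=1.0, w1=1.0, eps=1e-5)
        m2 = train(X, -y, C=1.0, w1=1.0, eps=1e-5)
        np.testing.assert_allclose(m1.w, -m2.w, atol=1e-3)
        assert m1.b == pytest.approx(-m2.b, abs=1e-3)

    def test_duplicating_samples_equals_doubling_C(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        y = np.where(X[:, 0] > 0.2, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        m_dup = train(np.vstack([X, X]), np.concatenate([y, y]), C=0.5, eps=1e-6)
        m_2c = train(X, y, C=1.0, eps=1e-6)
        np.testing.assert_allclose(m_dup.w, m_2c.w, atol=5e-3)

    @pytest.mark.parametrize("w1", [1.0, 2.5])
    def test_matches_libsvm_oracle(self, w1):
        from sklearn.svm import SVC

        rng = np.random.default_rng(3)
        X = rng.poisson(0.5, (120, 12)).astype(float)
        y = np.where(X[:, 0] + rng.normal(0, 0.5, 120) > 0.5, 1, -1)
        C = estimate_C(X)
        ours = train(X, y, C=C, w1=w1, eps=1e-5)
        ref = SVC(kernel="linear", C=C, class_weight={1: w1}, tol=1e-8).fit(X, y)
        np.testing.assert_allclose(ours.w, ref.coef_.ravel(), atol=1e-3)
        assert ours.b == pytest.approx(float(ref.intercept_[0]), abs=1e-3)

    def test_primal_feasibility_oracle(self):
        # the trained objective never exceeds that of random feasible probes
        rng = np.random.default_rng(4)
        X = rng.normal(size=(50, 4))
        y = np.where(X @ np.array([1.0, -1, 0.5, 0]) > 0, 1, -1)
        C, w1 = 0.7, 1.3

        def objective(w, b):
            xi = np.maximum(0.0, 1 - y * (X @ w + b))
            cvec = np.where(y > 0, C * w1, C)
            return 0.5 * w @ w + cvec @ xi

        model = train(X, y, C=C, w1=w1, eps=1e-6)
        ours = objective(model.w, model.b)
        for _ in range(200):
            w = model.w + rng.normal(0, 0.1, size=4)
            b = model.b + rng.normal(0, 0.1)
            assert ours <= objective(w, b) + 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train(np.eye(3), np.array([1, 1, 1]))


class TestDecisionScore:
    def test_linear_form(self):
        from promsig.svm import LinearModel

        m = LinearModel(np.array([1.0, 2.0]), -1.0, 1.0, 1.0)
        assert decision_score(m, np.array([1.0, 1.0])) == pytest.approx(2.0)
        assert decision_score(m, np.zeros(2)) == pytest.approx(-1.0)

    def test_additivity_identity(self):
        from promsig.svm import LinearModel

        rng = np.random.default_rng(5)
        m = LinearModel(rng.normal(size=4), 0.7, 1.0, 1.0)
        x, z = rng.normal(size=4), rng.normal(size=4)
        assert decision_score(m, x + z) == pytest.approx(
            decision_score(m, x) + decision_score(m, z) - m.b
        )

    def test_dimension_mismatch(self):
        from promsig.svm import LinearModel

        m = LinearModel(np.ones(3), 0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            decision_score(m, np.ones(2))


class TestClassWeight:
    def test_balancing_times_gamma(self):
        assert class_weight(100, 300, 1.0) == pytest.approx(3.0)
        assert class_weight(100, 300, 1 / 3) == pytest.approx(1.0)
        assert class_weight(100, 300, 1.0, flip=True) == pytest.approx(1 / 3)


def separable_matrix(n_promoters=6, per_promoter=3, n_neg=18, seed=0, flip_labels=False):
    """Positive promoters with elements carrying a strong first feature."""
    rng = np.random.default_rng(seed)
    X, y, proms = [], [], []
    for p in range(n_promoters):
        for _ in range(per_promoter):
            X.append([3.0 + rng.normal(0, 0.2), rng.normal(0, 0.2)])
            y.append(1)
            proms.append(f"P{p}")
    for i in range(n_neg):
        X.append([rng.normal(0, 0.2), rng.normal(0, 0.2)])
        y.append(-1)
        proms.append(f"N{i}")
    if flip_labels:
        y = list(rng.permutation(y))
    return make_matrix(X, y, proms)


class TestConsistentPositiveSet:
    def test_pick_two_per_promoter_when_all_positive(self):
        m = separable_matrix(n_promoters=3, per_promoter=3)
        rng = np.random.default_rng(0)
        chosen = build_consistent_positive_set(m, C=1.0, w1=1.0, rng=rng)
        assert len(chosen) == 6  # 2 per promoter
        assert all(m.y[i] == 1 for i in chosen)

    def test_promoter_with_single_positive_contributes_one(self):
        m = separable_matrix(n_promoters=3, per_promoter=1)
        chosen = build_consistent_positive_set(
            m, C=1.0, w1=1.0, rng=np.random.default_rng(0)
        )
        assert len(chosen) == 3

    def test_promoter_with_no_positive_scoring_contributes_none(self):
        # one promoter's elements are indistinguishable from negatives
        rng = np.random.default_rng(1)
        X, y, proms = [], [], []
        for p in range(3):
            for _ in range(3):
                X.append([3.0 + rng.normal(0, 0.1), 0.0])
                y.append(1)
                proms.append(f"P{p}")
        for _ in range(3):
            X.append([-3.0 + rng.normal(0, 0.1), 0.0])
            y.append(1)
            proms.append("Pbad")
        for i in range(12):
            X.append([-3.0 + rng.normal(0, 0.1), 0.0])
            y.append(-1)
            proms.append(f"N{i}")
        m = make_matrix(X, y, proms)
        chosen = build_consistent_positive_set(
            m, C=5.0, w1=1.0, rng=np.random.default_rng(0)
        )
        bad_rows = {i for i, r in enumerate(m.rows) if "Pbad" in r.promoter_of}
        assert not (set(chosen) & bad_rows)
        assert len(chosen) == 6

    def test_no_promoter_map_is_an_error(self):
        m = make_matrix([[1.0], [-1.0]], [1, -1])
        with pytest.raises(ValueError):
            build_consistent_positive_set(m, 1.0, 1.0, np.random.default_rng(0))


class TestDoubleLoopCV:
    def test_separable_data_reaches_perfect_median_auc(self):
        m = separable_matrix(n_promoters=10, per_promoter=3, n_neg=30)
        cfg = TrainConfig(repeats=2, seed=0)
        report = double_loop_cv(m, cfg)
        assert report.median_auc == pytest.approx(1.0)
        assert report.fold_aucs and max(report.fold_aucs) <= 1.0

    def test_consistent_set_sizes_bounded_by_pick_two(self):
        m = separable_matrix(n_promoters=10, per_promoter=3, n_neg=30)
        report = double_loop_cv(m, TrainConfig(repeats=1, seed=1))
        assert all(s <= 2 * 10 for s in report.consistent_set_sizes)

    def test_label_permutation_gives_chance_auc(self):
        medians = []
        for seed in range(8):
            m = separable_matrix(
                n_promoters=15, per_promoter=3, n_neg=45, seed=seed, flip_labels=True
            )
            cfg = TrainConfig(gamma_grid=(1.0,), repeats=1, seed=seed)
            medians.append(double_loop_cv(m, cfg).median_auc)
        assert abs(float(np.mean(medians)) - 0.5) < 0.12

    def test_deterministic_given_seed(self):
        m = separable_matrix()
        r1 = double_loop_cv(m, TrainConfig(repeats=1, seed=3))
        r2 = double_loop_cv(m, TrainConfig(repeats=1, seed=3))
        assert r1.fold_aucs == r2.fold_aucs
        assert r1.chosen_gamma == r2.chosen_gamma

    def test_too_few_members_rejected(self):
        m = make_matrix([[1.0], [2.0], [-1.0], [-2.0]], [1, 1, -1, -1])
        with pytest.raises(ValueError):
            double_loop_cv(m, TrainConfig())


class TestAuc:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [
            ([2, 3], [0, 1], 1.0),
            ([1, 1], [1, 1], 0.5),
            ([1], [0, 2], 0.5),
        ],
    )
    def test_examples(self, pos, neg, expected):
        assert auc(pos, neg) == pytest.approx(expected)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        st.lists(st.integers(0, 20), min_size=1, max_size=40),
        st.lists(st.integers(0, 20), min_size=1, max_size=40),
    )
    def test_matches_pair_enumeration(self, pos, neg):
        wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
        assert auc(pos, neg) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            auc([], [1])


class TestScaleWeights:
    @pytest.mark.parametrize(
        "w,expected",
        [
            ([2.0, -4.0, 0.0], [1.0, -1.0, 0.0]),
            ([2.0, -4.0, 1.0], [1.0, -1.0, 0.5]),
            ([3.0, -1.0], [1.0, -1.0]),
            ([0.0, 0.0], [0.0, 0.0]),
            ([-2.0, -4.0], [-0.5, -1.0]),
        ],
    )
    def test_printed_piecewise_formula(self, w, expected):
        sw = scale_weights(np.array(w))
        np.testing.assert_allclose(sw.scaled, expected, atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=30))
    def test_sign_pattern_preserved_and_bounded(self, w):
        sw = scale_weights(np.array(w))
        assert np.all(np.sign(sw.scaled) == np.sign(np.array(w)))
        assert np.all(np.abs(sw.scaled) <= 1 + 1e-12)


class TestReliability:
    @pytest.mark.parametrize(
        "median,expected",
        [(0.60, "reliable"), (0.59, "unreliable"), (0.98, "reliable")],
    )
    def test_cutoff_inclusive(self, median, expected):
        from promsig.svm import CVReport

        report = CVReport([median], 1.0, [1])
        assert is_reliable(report) == expected
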