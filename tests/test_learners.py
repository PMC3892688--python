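import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flystage.gabor import GroupStructure
from flystage.learners import (
    LinearModel,
    OneVsRestModel,
    SolverConfig,
    default_lambdas,
    fit_binary,
    fit_one_vs_rest,
    lambda_max,
    loss_value_and_gradient,
    objective_value,
    prox_group,
    prox_l1,
    prox_sparse_group,
)
from flystage.reference import reference_min_objective, reference_prox_objective


def _two_groups(d=6):
    return GroupStructure(groups=(np.arange(d // 2), np.arange(d // 2, d)))


class TestLosses:
    def test_logistic_loss_at_zero_weights_is_log_two(self, rng):
        X = rng.normal(size=(7, 3))
        y = np.where(rng.random(7) < 0.5, 1.0, -1.0)
        val, _ = loss_value_and_gradient("logistic", np.zeros(3), 0.0, X, y)
        assert val == pytest.approx(np.log(2.0), abs=1e-12)

    def test_least_square_loss_zero_at_perfect_fit(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, -0.5]])
        w = np.array([1.0, -1.0])  # X @ w reproduces the labels exactly
        y = np.array([1.0, -1.0, 1.0])
        val, _ = loss_value_and_gradient("least_square", w, 0.0, X, y)
        assert val == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("loss", ["least_square", "logistic"])
    def test_analytic_gradient_matches_central_differences(self, loss, rng):
        X = rng.normal(size=(5, 8))
        y = np.where(rng.random(5) < 0.5, 1.0, -1.0)
        w, b = rng.normal(size=8), 0.3
        _, grad = loss_value_and_gradient(loss, w, b, X, y)
        eps = 1e-6
        num = np.empty(9)
        for j in range(9):
            def at(delta):
                wj = w.copy()
                bj = b
                if j < 8:
                    wj[j] += delta
                else:
                    bj += delta
                return loss_value_and_gradient(loss, wj, bj, X, y)[0]
            num[j] = (at(eps) - at(-eps)) / (2 * eps)
        np.testing.assert_allclose(grad, num, atol=1e-5)

    def test_unknown_loss_rejected(self):
        with pytest.raises(ValueError):
            loss_value_and_gradient("huber", np.zeros(2), 0.0, np.zeros((1, 2)), np.array([1.0]))


class TestProxOperators:
    @pytest.mark.parametrize("v,t,expected", [(2.0, 0.5, 1.5), (0.3, 0.5, 0.0), (-2.0, 0.5, -1.5)])
    def test_soft_threshold_examples(self, v, t, expected):
        assert prox_l1(np.array([v]), t)[0] == pytest.approx(expected)

    def test_group_shrinkage_example(self):
        out = prox_group(np.array([3.0, 4.0]), 1.0, GroupStructure(groups=(np.arange(2),)))
        np.testing.assert_allclose(out, [2.4, 3.2])

    def test_group_inside_threshold_is_zeroed(self):
        v = np.array([0.5, 0.5, 0.5])  # norm ~0.87 < 1
        out = prox_group(v, 1.0, GroupStructure(groups=(np.arange(3),)))
        np.testing.assert_array_equal(out, 0.0)

    def test_zero_threshold_is_identity(self, rng):
        v = rng.normal(size=6)
        np.testing.assert_array_equal(prox_group(v, 0.0, _two_groups()), v)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            prox_l1(np.ones(3), -0.1)

    def test_sparse_group_reduces_to_l1_when_group_weight_zero(self, rng):
        v = rng.normal(size=6) * 2
        np.testing.assert_array_equal(
            prox_sparse_group(v, 0.7, 0.0, _two_groups()), prox_l1(v, 0.7)
        )

    def test_sparse_group_reduces_to_group_when_l1_weight_zero(self, rng):
        v = rng.normal(size=6) * 2
        np.testing.assert_array_equal(
            prox_sparse_group(v, 0.0, 0.9, _two_groups()), prox_group(v, 0.9, _two_groups())
        )

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 2.0), st.floats(0.0, 2.0))
    def test_prox_achieves_numeric_minimum(self, seed, t1, t2):
        gen = np.random.default_rng(seed)
        v = gen.normal(size=6) * 2
        groups = _two_groups()
        u = prox_sparse_group(v, t1, t2, groups)

        def obj(u_):
            return (
                0.5 * np.sum((u_ - v) ** 2)
                + t1 * np.abs(u_).sum()
                + t2 * sum(np.linalg.norm(u_[g]) for g in groups.groups)
            )

        _, ref = reference_prox_objective(v, t1, t2, groups)
        assert obj(u) <= ref + 1e-6

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.floats(0.0, 3.0))
    def test_soft_threshold_shrinks_toward_zero(self, seed, t):
        v = np.random.default_rng(seed).normal(size=8) * 3
        u = prox_l1(v, t)
        assert np.all(np.abs(u) <= np.abs(v) + 1e-15)
        assert np.all(u * v >= 0)


class TestFitBinary:
    def test_lasso_at_lambda_max_gives_all_zero_weights(self, rng):
        X = rng.normal(size=(30, 10))
        y = np.where(rng.random(30) < 0.5, 1.0, -1.0)
        lmax = lambda_max(X, y, "least_square", "l1")
        m = fit_binary(X, y, "least_square", "l1", lambda1=lmax * 1.0001, lambda2=0.0)
        np.testing.assert_allclose(m.weights, 0.0, atol=1e-10)

    def test_lasso_below_lambda_max_has_nonzero_weights(self, rng):
        X = rng.normal(size=(30, 10))
        w_true = np.zeros(10)
        w_true[:3] = 2.0
        y = np.sign(X @ w_true + 0.1 * rng.normal(size=30))
        lmax = lambda_max(X, y, "least_square", "l1")
        m = fit_binary(X, y, "least_square", "l1", lambda1=0.01 * lmax, lambda2=0.0)
        assert np.any(m.weights != 0)

    def test_separable_logistic_ridge_reaches_perfect_training_accuracy(self):
        X = np.vstack([np.full((10, 2), -2.0), np.full((10, 2), 2.0)])
        y = np.concatenate([-np.ones(10), np.ones(10)])
        m = fit_binary(X, y, "logistic", "l2", lambda2=1e-3)
        assert np.mean(m.predict(X) == y) == 1.0

    @pytest.mark.parametrize(
        "loss,reg",
        [("least_square", "l1"), ("logistic", "group_l1l2"), ("logistic", "sparse_group"),
         ("hinge", "l2")],
    )
    def test_objective_matches_independent_minimizer(self, loss, reg, rng):
        X = rng.normal(size=(30, 10))
        y = np.sign(X @ rng.normal(size=10) + 0.2 * rng.normal(size=30))
        y[y == 0] = 1
        groups = GroupStructure(groups=(np.arange(5), np.arange(5, 10)))
        m = fit_binary(X, y, loss, reg, groups=groups,
                       config=SolverConfig(max_iter=5000, tol=1e-9))
        ours = objective_value(m, X=X, y=y)
        _, _, ref = reference_min_objective(X, y, loss, reg, m.lambda1, m.lambda2, groups)
        assert ours == pytest.approx(ref, abs=1e-5 * max(1.0, abs(ref)))

    def test_objective_history_is_non_increasing(self, rng):
        X = rng.normal(size=(40, 12))
        y = np.sign(rng.normal(size=40))
        y[y == 0] = 1
        m = fit_binary(X, y, "logistic", "l1", config=SolverConfig(max_iter=200, tol=1e-12))
        hist = np.array(m.objective_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_group_lasso_zeroes_whole_groups(self, rng):
        X = rng.normal(size=(40, 12))
        w_true = np.zeros(12)
        w_true[:3] = 3.0  # only group 0 informative
        y = np.sign(X @ w_true + 0.1 * rng.normal(size=40))
        groups = GroupStructure(groups=tuple(np.arange(i * 3, (i + 1) * 3) for i in range(4)))
        strength = 0.5 * lambda_max(X, y, "least_square", "group", groups)
        m = fit_binary(X, y, "least_square", "group_l1l2", lambda2=strength, groups=groups,
                       config=SolverConfig(max_iter=2000, tol=1e-10))
        for g in groups.groups:
            block = m.weights[g]
            assert np.all(block == 0) or np.all(block != 0)
        assert np.any(m.weights == 0) and np.any(m.weights != 0)

    def test_hinge_requires_l2_regularizer(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.sign(rng.normal(size=10))
        y[y == 0] = 1
        with pytest.raises(ValueError):
            fit_binary(X, y, "hinge", "l1")

    def test_default_lambdas_scale_with_lambda_max(self, rng):
        X = rng.normal(size=(25, 8))
        y = np.sign(rng.normal(size=25))
        y[y == 0] = 1
        l1, l2 = default_lambdas(X, y, "least_square", "l1", None)
        assert l1 == pytest.approx(0.01 * lambda_max(X, y, "least_square", "l1"))
        assert l2 == 0.0


class TestOneVsRest:
    def test_fifteen_class_problem_trains_fifteen_models(self, blob_data):
        X, stages = blob_data
        ovr = fit_one_vs_rest(X[:60], stages[:60], "least_square", "l2", lambda2=0.1,
                              classes=np.arange(3, 18))
        assert len(ovr.models) == 15
        np.testing.assert_array_equal(ovr.classes, np.arange(3, 18))

    def test_all_equal_decision_values_predict_smallest_stage(self):
        models = tuple(
            LinearModel(weights=np.zeros(2), intercept=0.5, loss_name="least_square",
                        regularizer_name="l2")
            for _ in range(15)
        )
        ovr = OneVsRestModel(classes=np.arange(3, 18), models=models)
        assert ovr.predict(np.zeros((1, 2)))[0] == 3

    def test_well_separated_blobs_classified_accurately(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels = np.repeat([3, 4, 5], 30)
        X = centers[labels - 3] + rng.normal(scale=0.5, size=(90, 2))
        ovr = fit_one_vs_rest(X, labels, "logistic", "l2", lambda2=1e-3)
        assert np.mean(ovr.predict(X) == labels) >= 0.95

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_one_vs_rest(X, np.full(10, 7), "logistic", "l2")
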