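import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from esometh.diagnostic import (
    DiagnosticModel,
    GroupedLassoConfig,
    cv_select_lambda,
    fit_final_multinomial,
    fit_grouped_multinomial_lasso,
    kkt_residuals,
    lambda_max,
    one_se_lambda,
    penalized_objective,
    stability_select,
    _one_hot,
    _softmax,
    _standardize,
)
from esometh.exceptions import StratificationError, ValidationError


def make_multiclass(seed=0, n=120, p=12, k=4, n_informative=3, scale=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    B = np.zeros((p, k))
    B[:n_informative] = rng.normal(scale=scale, size=(n_informative, k))
    y = np.array([f"c{j}" for j in range(k)])[
        np.argmax(X @ B + rng.normal(size=(n, k)), axis=1)
    ]
    return X, y


def oracle_min_objective(X, y, lam, seed=0):
    """Generic convex solve of the grouped-lasso objective via the smooth
    epigraph formulation  min nll + lam * sum t_j  s.t.  t_j^2 >= ||B_j||^2."""
    Xs, _, _ = _standardize(X)
    classes = np.unique(y)
    Y = _one_hot(y, classes)
    n, p = Xs.shape
    K = len(classes)

    def unpack(z):
        B = z[: p * K].reshape(p, K)
        b0 = z[p * K : p * K + K]
        t = z[p * K + K :]
        return B, b0, t

    def fun(z):
        B, b0, t = unpack(z)
        Z = Xs @ B + b0
        Z = Z - Z.max(axis=1, keepdims=True)
        log_p = Z - np.log(np.exp(Z).sum(axis=1, keepdims=True))
        return -np.sum(log_p * Y) / n + lam * t.sum()

    cons = [
        {
            "type": "ineq",
            "fun": (lambda z, j=j: unpack(z)[2][j] ** 2 - (unpack(z)[0][j] ** 2).sum()),
        }
        for j in range(p)
    ] + [{"type": "ineq", "fun": (lambda z, j=j: unpack(z)[2][j])} for j in range(p)]
    rng = np.random.default_rng(seed)
    z0 = np.concatenate([rng.normal(scale=0.1, size=p * K + K), np.ones(p)])
    res = optimize.minimize(
        fun, z0, method="SLSQP", constraints=cons,
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    return res.fun


class TestGroupedLassoSolver:
    def test_lambda_max_zeroes_everything(self):
        X, y = make_multiclass(seed=1)
        lmax = lambda_max(X, y)
        fit = fit_grouped_multinomial_lasso(X, y, lmax * 1.0001)
        assert len(fit.active_features) == 0
        freq = np.array([np.mean(y == c) for c in fit.classes])
        expected = np.log(freq) - np.mean(np.log(freq))
        np.testing.assert_allclose(fit.intercept, expected, atol=1e-5)

    @pytest.mark.parametrize("frac", [0.5, 0.2, 0.05])
    def test_kkt_conditions_hold(self, frac):
        X, y = make_multiclass(seed=2, p=15)
        lam = frac * lambda_max(X, y)
        fit = fit_grouped_multinomial_lasso(X, y, lam, kkt_tol=1e-8)
        resid = kkt_residuals(X, y, fit)
        assert resid["zero_groups"] <= 1e-6
        assert resid["active_groups"] <= 1e-6
        assert resid["intercepts"] <= 1e-6

    def test_matches_generic_convex_solver_on_tiny_instance(self):
        """Objective value agrees with an SLSQP epigraph solve to 1e-5 relative."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        y = np.array(["a", "b", "c"] * 4)
        lam = 0.3 * lambda_max(X, y)
        fit = fit_grouped_multinomial_lasso(X, y, lam, kkt_tol=1e-10)
        oracle = oracle_min_objective(X, y, lam)
        assert fit.objective == pytest.approx(oracle, rel=1e-5, abs=1e-7)

    def test_support_grows_as_lambda_shrinks(self):
        X, y = make_multiclass(seed=4)
        lmax = lambda_max(X, y)
        sizes = [
            len(fit_grouped_multinomial_lasso(X, y, f * lmax).active_features)
            for f in (1.1, 0.5, 0.05, 0.005)
        ]
        assert sizes[0] == 0
        assert sizes == sorted(sizes)

    def test_sample_order_invariance(self):
        X, y = make_multiclass(seed=5, n=60)
        fit1 = fit_grouped_multinomial_lasso(X, y, 0.1, kkt_tol=1e-9)
        perm = np.random.default_rng(0).permutation(len(y))
        fit2 = fit_grouped_multinomial_lasso(X[perm], y[perm], 0.1, kkt_tol=1e-9)
        np.testing.assert_allclose(fit1.coef, fit2.coef, atol=1e-5)

    def test_invalid_inputs_rejected(self):
        X, y = make_multiclass(seed=6, n=30)
        with pytest.raises(ValidationError):
            fit_grouped_multinomial_lasso(X, y, -0.1)
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_grouped_multinomial_lasso(X, y, 0.1)


class TestCVSelectLambda:
    def test_one_se_rule_on_recorded_table(self):
        table = pd.DataFrame(
            {
                "lam": [1.0, 0.5, 0.1],
                "mean_accuracy": [0.85, 0.89, 0.90],
                "se_accuracy": [0.01, 0.015, 0.02],
            }
        )
        assert one_se_lambda(table) == 0.5

    def test_equal_accuracies_give_largest_lambda(self):
        table = pd.DataFrame(
            {"lam": [1.0, 0.5, 0.1], "mean_accuracy": [0.8] * 3, "se_accuracy": [0.02] * 3}
        )
        assert one_se_lambda(table) == 1.0

    def test_selected_lambda_satisfies_rule_against_its_table(self):
        X, y = make_multiclass(seed=7, n=100, p=10)
        cv = cv_select_lambda(X, y, n_folds=5, grid_size=30, seed=1)
        t = cv.table
        best = t["mean_accuracy"].idxmax()
        thr = t.loc[best, "mean_accuracy"] - t.loc[best, "se_accuracy"]
        qualifying = t.loc[t["mean_accuracy"] >= thr, "lam"]
        assert cv.lambda_selected == qualifying.max()

    def test_missing_class_in_fold_raises(self):
        X = np.random.default_rng(0).normal(size=(12, 3))
        y = np.array(["a"] * 10 + ["b"] * 2)
        with pytest.raises((StratificationError, ValueError)):
            cv_select_lambda(X, y, n_folds=5, grid_size=5, seed=0)


class TestStabilitySelect:
    def test_single_partition_equals_single_fit_support(self, esophageal_xy):
        X, y, _ = esophageal_xy
        X = X.iloc[:, :60]
        cfg = GroupedLassoConfig(
            n_partitions=1, freq_threshold=1, n_folds=5, grid_size=20, seed=3
        )
        sel = stability_select(X, y, cfg)
        assert set(sel.selected) == set(sel.frequencies.index[sel.frequencies == 1])
        assert sel.frequencies.max() <= 1

    def test_threshold_above_partitions_selects_nothing(self, esophageal_xy):
        X, y, _ = esophageal_xy
        X = X.iloc[:, :40]
        cfg = GroupedLassoConfig(
            n_partitions=2, freq_threshold=3, n_folds=5, grid_size=15, seed=4
        )
        sel = stability_select(X, y, cfg)
        assert sel.selected == []

    def test_feature_order_invariance(self, esophageal_xy):
        X, y, _ = esophageal_xy
        X = X.iloc[:, :30]
        cfg = GroupedLassoConfig(n_partitions=2, freq_threshold=2, n_folds=5, grid_size=15, seed=5)
        f1 = stability_select(X, y, cfg).frequencies
        shuffled = X.iloc[:, ::-1]
        f2 = stability_select(shuffled, y, cfg).frequencies
        pd.testing.assert_series_equal(f1.sort_index(), f2.sort_index())

    def test_too_few_training_samples_per_class_raises(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 4)))
        y = np.array(["a", "b", "c", "d"] * 3)
        with pytest.raises(StratificationError):
            stability_select(X, y, GroupedLassoConfig(n_folds=10))


class TestFinalModel:
    def test_perfectly_ordered_single_feature(self):
        X = pd.DataFrame({"cg1": [0.1, 0.4, 0.7, 1.0]})
        y = np.array(["a", "b", "c", "d"])
        model = fit_final_multinomial(X, y, ridge=1e-8)
        assert (model.predict(X) == y).all()

    def test_planted_training_accuracy(self, esophageal_xy):
        X, y, truth = esophageal_xy
        panel = sorted(truth.all_specific)
        model = fit_final_multinomial(X[panel], y)
        acc = (model.predict(X[panel]) == y).mean()
        assert acc >= 0.9

    def test_serialization_round_trip_is_exact(self, esophageal_xy, tmp_path):
        X, y, truth = esophageal_xy
        panel = sorted(truth.all_specific)[:6]
        model = fit_final_multinomial(X[panel], y)
        path = tmp_path / "model.json"
        model.to_json(path)
        restored = DiagnosticModel.from_json(path)
        p1 = model.predict_proba(X[panel]).to_numpy()
        p2 = restored.predict_proba(X[panel]).to_numpy()
        np.testing.assert_array_equal(p1, p2)

    def test_empty_selection_raises_actionable_error(self):
        with pytest.raises(ValidationError, match="threshold"):
            fit_final_multinomial(pd.DataFrame(index=[0, 1]), np.array(["a", "b"]))


class TestPredictProba:
    def test_zero_coefficients_give_uniform(self):
        model = DiagnosticModel(
            classes=["a", "b", "c", "d"],
            cpgs=["cg1", "cg2"],
            intercept=np.zeros(4),
            coef=np.zeros((2, 4)),
            scaler_mean=np.zeros(2),
            scaler_scale=np.ones(2),
        )
        X = pd.DataFrame(np.random.default_rng(0).random((5, 2)), columns=["cg1", "cg2"])
        np.testing.assert_allclose(model.predict_proba(X).to_numpy(), 0.25)

    def test_rows_sum_to_one_and_argmax_is_predict(self, esophageal_xy):
        X, y, truth = esophageal_xy
        panel = sorted(truth.all_specific)[:5]
        model = fit_final_multinomial(X[panel], y)
        probs = model.predict_proba(X[panel])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)
        assert (probs.idxmax(axis=1) == model.predict(X[panel])).all()

    def test_missing_cpg_named(self, esophageal_xy):
        X, y, truth = esophageal_xy
        panel = sorted(truth.all_specific)[:4]
        model = fit_final_multinomial(X[panel], y)
        with pytest.raises(ValidationError, match=panel[0]):
            model.predict_proba(X.drop(columns=panel[0]))
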