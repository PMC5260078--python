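"""The two-stage age regressor: Lasso stage, gene ranking, stepwise PLS, folds."""

import numpy as np
import pandas as pd
import pytest

from isap import (
    IsapHyperparams,
    evaluate,
    fit_isap,
    fit_lasso_stage,
    fit_stepwise_pls_stage,
    make_folds,
    predict,
    predict_flat,
    rank_genes_by_residual_correlation,
)
from isap.preprocess import preprocess_dataset
from isap.simulate import SimulationConfig, generate_cohort


def _kfolds(n, k=5, seed=0):
    return make_folds(range(n), scheme="kfold", k=k, seed=seed)


class TestLassoStage:
    def test_exact_sparse_recovery_at_tiny_penalty(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 8)), columns=[f"p{i}" for i in range(8)])
        y = 2.0 * X["p0"].to_numpy()
        hyper = IsapHyperparams(lambda_grid=(1e-4,))
        coefs, _, resid, lam = fit_lasso_stage(X, y, hyper, _kfolds(100))
        assert abs(coefs["p0"] - 2.0) < 0.05
        assert np.all(np.abs(coefs.drop("p0")) < 0.05)

    def test_infinite_penalty_shrinks_everything_to_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 5)))
        y = rng.normal(size=50)
        hyper = IsapHyperparams(lambda_grid=(1e6,))
        coefs, intercept, resid, _ = fit_lasso_stage(X, y - y.mean(), hyper, _kfolds(50))
        assert np.all(coefs == 0)
        assert np.allclose(resid, y - y.mean() - intercept)

    def test_objective_matches_projected_subgradient_oracle(self, rng):
        """Tiny instance: compare the attained objective with a brute-force solver."""
        n, p, lam = 10, 3, 0.1
        X = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        yc = y - y.mean()

        def objective(beta):
            r = yc - X @ beta
            return r @ r / (2 * n) + lam * np.abs(beta).sum()

        # projected subgradient descent from zero, diminishing step
        beta = np.zeros(p)
        best = objective(beta)
        best_beta = beta.copy()
        for t in range(1, 40001):
            grad = -X.T @ (yc - X @ beta) / n + lam * np.sign(beta)
            beta = beta - (0.5 / np.sqrt(t)) * grad
            val = objective(beta)
            if val < best:
                best, best_beta = val, beta.copy()
        hyper = IsapHyperparams(lambda_grid=(lam,))
        coefs, _, _, _ = fit_lasso_stage(pd.DataFrame(X), yc, hyper, _kfolds(n, k=2))
        assert objective(coefs.to_numpy()) <= best + 1e-4

    def test_cv_picks_lambda_minimizing_cv_error(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 10)))
        y = 3.0 * X[0].to_numpy() + 0.1 * rng.normal(size=60)
        hyper = IsapHyperparams(lambda_grid=(1e-3, 1e3))
        _, _, _, lam = fit_lasso_stage(X, y, hyper, _kfolds(60))
        assert lam == 1e-3


class TestGeneRanking:
    def test_gene_equal_to_residuals_ranks_first(self, rng):
        expr = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        ranked = rank_genes_by_residual_correlation(expr, expr["c"].to_numpy())
        assert ranked[0] == "c"

    def test_constructed_correlation_order(self, rng):
        n = 4000
        z = rng.normal(size=n)
        targets = {"g1": 0.9, "g2": -0.8, "g3": 0.3, "g4": 0.0, "g5": 0.5}
        cols = {
            g: r * z + np.sqrt(max(1 - r**2, 1e-12)) * rng.normal(size=n)
            for g, r in targets.items()
        }
        ranked = rank_genes_by_residual_correlation(pd.DataFrame(cols), z)
        assert ranked == ["g1", "g2", "g5", "g3", "g4"]

    def test_deterministic_under_fixed_input(self, rng):
        expr = pd.DataFrame(rng.normal(size=(80, 20)))
        resid = rng.normal(size=80)
        assert rank_genes_by_residual_correlation(expr, resid) == \
            rank_genes_by_residual_correlation(expr, resid)

    def test_zero_variance_residuals_skip_stage(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 3)))
        assert rank_genes_by_residual_correlation(expr, np.zeros(20)) == []


class TestStepwisePls:
    def test_one_gene_truth(self, rng):
        expr = pd.DataFrame(rng.normal(size=(60, 10)), columns=[f"g{i}" for i in range(10)])
        resid = expr["g0"].to_numpy()
        ranked = rank_genes_by_residual_correlation(expr, resid)
        hyper = IsapHyperparams(max_genes=5, max_pls_components=3)
        selected, pls, ncomp = fit_stepwise_pls_stage(expr, resid, ranked, hyper, _kfolds(60))
        assert selected == ["g0"] and ncomp == 1

    def test_pure_noise_takes_fallback_most_of_the_time(self):
        """Under the null, honest CV should usually prefer the intercept."""
        fallbacks = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            expr = pd.DataFrame(r.normal(size=(60, 40)))
            resid = r.normal(size=60)
            ranked = rank_genes_by_residual_correlation(expr, resid)
            hyper = IsapHyperparams(max_genes=10, max_pls_components=3)
            selected, _, _ = fit_stepwise_pls_stage(expr, resid, ranked, hyper, _kfolds(60, seed=seed))
            fallbacks += not selected
        assert fallbacks >= 5

    def test_recovers_planted_genes_among_noise(self):
        r = np.random.default_rng(1)
        n = 200
        expr = pd.DataFrame(r.normal(size=(n, 100)), columns=[f"g{i}" for i in range(100)])
        resid = (expr["g3"] + expr["g40"] - expr["g77"]).to_numpy() + 0.5 * r.normal(size=n)
        ranked = rank_genes_by_residual_correlation(expr, resid)
        hyper = IsapHyperparams(max_genes=15, max_pls_components=5)
        selected, _, _ = fit_stepwise_pls_stage(expr, resid, ranked, hyper, _kfolds(n, seed=1))
        assert {"g3", "g40", "g77"} <= set(selected)


class TestFolds:
    def test_one_fold_per_tissue(self):
        tissues = np.repeat([f"t{i}" for i in range(6)], 10)
        folds = make_folds(range(60), tissues=tissues, scheme="loto")
        assert len(folds) == 6
        for fold, label in zip(folds, sorted(set(tissues))):
            assert set(tissues[fold]) == {label}

    def test_kfold_even_sizes(self):
        folds = make_folds(range(10), scheme="kfold", k=5, seed=0)
        assert sorted(len(f) for f in folds) == [2] * 5
        assert sorted(np.concatenate(folds)) == list(range(10))

    def test_kfold_seeded_determinism(self):
        a = make_folds(range(23), scheme="kfold", k=4, seed=9)
        b = make_folds(range(23), scheme="kfold", k=4, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            make_folds(range(3), scheme="kfold", k=5)


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate([1.0, 2.0], [1.0, 2.0])
        row = rep.iloc[0]
        assert row["residual_error"] == 0 and row["median_error"] == 0
        assert row["correlation"] == pytest.approx(1.0)

    def test_constant_predictions_flag_undefined_correlation(self):
        rep = evaluate([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        row = rep.iloc[0]
        assert np.isnan(row["correlation"])
        assert row["residual_error"] == (4**2 + 3**2 + 2**2)

    def test_shifted_predictions_hand_arithmetic(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = evaluate(y + 1, y)
        row = rep.iloc[0]
        assert row["residual_error"] == 4 and row["median_error"] == 1 and row["correlation"] == 1


@pytest.fixture(scope="module")
def fitted():
    cfg = SimulationConfig(n_tissues=4, samples_per_tissue=50, n_meth_features=80,
                           n_expr_features=80, seed=21)
    ds = preprocess_dataset(generate_cohort(cfg))
    train = list(ds.meta.index[ds.meta["tissue"] != "tissue_03"])
    model, markers = fit_isap(ds, IsapHyperparams(seed=0), train_samples=train)
    return cfg, ds, train, model, markers


class TestFitPredict:

    def test_staged_and_flattened_predictions_agree(self, fitted, rng):
        _, ds, _, model, _ = fitted
        meth = pd.DataFrame(rng.normal(size=(100, ds.meth.shape[1])), columns=ds.meth.columns)
        expr = pd.DataFrame(rng.normal(size=(100, ds.expr.shape[1])), columns=ds.expr.columns)
        assert np.max(np.abs(predict(model, meth, expr) - predict_flat(model, meth, expr))) < 1e-8

    def test_mean_level_input_predicts_train_mean_plus_intercepts(self, fitted):
        _, ds, _, model, _ = fitted
        meth = pd.DataFrame(np.zeros((1, ds.meth.shape[1])), columns=ds.meth.columns)
        expr = pd.DataFrame(np.zeros((1, ds.expr.shape[1])), columns=ds.expr.columns)
        expected = model.train_age_mean + model.combined_intercept
        assert np.allclose(predict(model, meth, expr), expected)

    def test_refit_with_same_seed_is_identical(self, fitted):
        cfg, ds, train, model, markers = fitted
        model2, markers2 = fit_isap(ds, IsapHyperparams(seed=0), train_samples=train)
        pd.testing.assert_frame_equal(markers.table, markers2.table)
        assert model.lambda_chosen == model2.lambda_chosen

    def test_marker_set_sorted_by_absolute_weight(self, fitted):
        *_, markers = fitted
        w = markers.table["weight"].abs().to_numpy()
        assert np.all(w[:-1] >= w[1:])
        assert list(markers.table["rank"]) == list(range(1, len(w) + 1))

    def test_missing_model_features_raise(self, fitted):
        _, ds, _, model, _ = fitted
        with pytest.raises(KeyError):
            predict(model, ds.meth.iloc[:, :2], ds.expr)
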