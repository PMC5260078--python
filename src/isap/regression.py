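"""The ISAP age regressor.

Two-stage integration of paired omics matrices against (train-centred)
chronological age:

1. Lasso on the methylation matrix, penalty chosen by cross-validation over a
   grid; the in-sample residuals are carried forward.
2. Expression genes are ranked by absolute Pearson correlation with the
   residuals; a forward-stepwise loop grows the candidate set along that
   ranking, compressing each candidate set with single-response PLS (NIPALS)
   and scoring it by cross-validated squared error.  The number of genes is
   chosen first (at the maximal admissible component count), then the number
   of PLS components at the chosen gene count.
3. The final predictor is the sum of both stages; its flattened per-feature
   weights (the "aging markers" with their regression coefficients) are the
   composition of the PLS projection and the component regression.

Cross-validation folds follow the multi-tissue design: leave-one-tissue-out
("one fold per training tissue"), or a seeded k-fold for single-tissue models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import Lasso

from .data import OmicsDataset
from .preprocess import center_ages

log = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 1, 25))


@dataclass
class IsapHyperparams:
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    max_genes: int = 20
    max_pls_components: int = 5
    cv_scheme: str = "loto"  # "loto" or "kfold"
    n_folds: int = 5  # used by the kfold scheme
    cv_residuals: bool = False  # carry CV residuals (not in-sample) into stage 2
    seed: int = 0

    def validate(self) -> None:
        if len(self.lambda_grid) == 0 or min(self.lambda_grid) <= 0:
            raise ValueError("lambda_grid must be non-empty and strictly positive")
        if self.max_genes < 1:
            raise ValueError("max_genes must be positive")
        if not 1 <= self.max_pls_components <= self.max_genes:
            raise ValueError("max_pls_components must be in [1, max_genes]")
        if self.cv_scheme not in ("loto", "kfold"):
            raise ValueError(f"unknown cv_scheme {self.cv_scheme!r}")


@dataclass
class IsapModel:
    """Fitted pipeline state; see :func:`predict` for how it is applied."""

    meth_coefs: pd.Series  # probe -> years per SD unit (nonzero entries = markers)
    lasso_intercept: float
    lambda_chosen: float
    selected_genes: list[str]  # correlation-rank order
    pls_x_mean: np.ndarray  # per-gene centring of the PLS stage
    pls_x_weights: np.ndarray  # genes x components
    pls_coef: np.ndarray  # flattened per-gene regression coefficients
    pls_intercept: float
    n_components: int
    train_age_mean: float

    @property
    def combined_weights(self) -> pd.Series:
        """(modality, feature) -> final regression coefficient (flattened)."""
        idx = [("methylation", p) for p in self.meth_coefs.index] + [
            ("expression", g) for g in self.selected_genes
        ]
        vals = np.concatenate([self.meth_coefs.to_numpy(), self.pls_coef])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx, names=["modality", "feature"]))

    @property
    def combined_intercept(self) -> float:
        return self.lasso_intercept + self.pls_intercept


def make_folds(samples, tissues=None, scheme: str = "loto", k: int = 5, seed: int = 0):
    """Return a list of held-out index arrays partitioning ``samples``.

    ``loto``: one fold per tissue (the multi-tissue design, "6-fold" when six
    training tissues).  ``kfold``: seeded random partition with fold sizes
    differing by at most one.
    """
    n = len(samples)
    if scheme == "loto":
        if tissues is None:
            raise ValueError("leave-one-tissue-out folds need tissue labels")
        tissues = np.asarray(tissues)
        labels = sorted(pd.unique(tissues))
        if len(labels) < 2:
            raise ValueError("leave-one-tissue-out needs at least 2 tissues")
        return [np.flatnonzero(tissues == t) for t in labels]
    if scheme == "kfold":
        if k > n:
            raise ValueError(f"k={k} exceeds the number of samples ({n})")
        perm = np.random.default_rng(seed).permutation(n)
        return [np.sort(chunk) for chunk in np.array_split(perm, k)]
    raise ValueError(f"unknown fold scheme {scheme!r}")


def _cv_mse(fit_predict, X, y, folds) -> float:
    """Pooled held-out squared error of a fit/predict callable over folds."""
    n = len(y)
    pred = np.empty(n)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        pred[test_idx] = fit_predict(X[train_idx], y[train_idx], X[test_idx])
    return float(np.mean((pred - y) ** 2))


def fit_lasso_stage(meth: pd.DataFrame, centered_age, hyper: IsapHyperparams, folds):
    """Stage 1: CV-selected Lasso of centred age on methylation.

    Returns ``(meth_coefs, lasso_intercept, residuals, lambda_chosen)`` with
    residuals = centred age minus in-sample predictions (or CV predictions if
    ``hyper.cv_residuals``).
    """
    hyper.validate()
    y = np.asarray(centered_age, dtype=float)
    X = meth.to_numpy(dtype=float)
    if len(folds) > len(y):
        raise ValueError("fewer samples than folds")

    def lasso_fp(alpha):
        def fp(Xtr, ytr, Xte):
            m = Lasso(alpha=alpha, max_iter=50_000)
            m.fit(Xtr, ytr)
            return m.predict(Xte)

        return fp

    cv_errors = {lam: _cv_mse(lasso_fp(lam), X, y, folds) for lam in hyper.lambda_grid}
    lambda_chosen = min(cv_errors, key=lambda lam: (cv_errors[lam], lam))
    model = Lasso(alpha=lambda_chosen, max_iter=50_000)
    model.fit(X, y)
    if not np.any(model.coef_):
        log.warning("Lasso solution is all-zero at every grid point; keeping largest-penalty model")
    coefs = pd.Series(model.coef_, index=meth.columns)
    if hyper.cv_residuals:
        resid = np.empty_like(y)
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
            m = Lasso(alpha=lambda_chosen, max_iter=50_000)
            m.fit(X[train_idx], y[train_idx])
            resid[test_idx] = y[test_idx] - m.predict(X[test_idx])
    else:
        resid = y - model.predict(X)
    return coefs, float(model.intercept_), resid, float(lambda_chosen)


def rank_genes_by_residual_correlation(expr: pd.DataFrame, residuals) -> list[str]:
    """Genes sorted by |Pearson r| with the residuals, descending.

    Ties (and zero-variance genes, r treated as 0) keep the input column
    order.  Zero-variance residuals — a perfect stage-1 fit — return an empty
    ranking, which signals the stepwise stage to be skipped.
    """
    r = np.asarray(residuals, dtype=float)
    if np.std(r) == 0:
        log.warning("residuals have zero variance (perfect Lasso fit); skipping stepwise stage")
        return []
    X = expr.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    rc = r - r.mean()
    denom = np.sqrt((Xc**2).sum(axis=0) * (rc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, Xc.T @ rc / np.where(denom > 0, denom, 1.0), 0.0)
    order = np.argsort(-np.abs(corr), kind="stable")
    return [expr.columns[i] for i in order]


def _fit_pls(X, y, n_components: int) -> PLSRegression:
    n_components = max(1, min(n_components, X.shape[1], X.shape[0] - 1))
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y.reshape(-1, 1))
    return pls


def _pls_fp(n_components):
    def fp(Xtr, ytr, Xte):
        pls = _fit_pls(Xtr, ytr, n_components)
        return pls.predict(Xte).ravel()

    return fp


def fit_stepwise_pls_stage(expr: pd.DataFrame, residuals, ranked_genes, hyper: IsapHyperparams, folds):
    """Stage 2: forward stepwise gene count, then PLS component count, by CV.

    The candidate set grows along the correlation ranking; every candidate
    count g is scored by cross-validated squared error of a PLS1 fit with the
    maximal admissible component count.  To keep the CV honest, the ranking
    itself is recomputed inside each training fold (ranking on the full data
    would leak the held-out samples into the selection and make pure noise
    look predictive).  An intercept-only baseline (g=0) competes; if nothing
    beats it the stage returns an empty selection and the predictor falls
    back to stage 1 alone.

    Returns ``(selected_genes, fitted PLS or None, n_components)``.
    """
    hyper.validate()
    y = np.asarray(residuals, dtype=float)
    if not ranked_genes:
        return [], None, 0
    n = len(y)
    baseline = _cv_mse(lambda Xtr, ytr, Xte: np.full(len(Xte), ytr.mean()), np.zeros((n, 1)), y, folds)

    X_all = expr.to_numpy(dtype=float)
    col_idx = {g: i for i, g in enumerate(expr.columns)}
    fold_rankings = []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        fold_rank = rank_genes_by_residual_correlation(expr.iloc[train_idx], y[train_idx])
        fold_rankings.append((train_idx, test_idx, [col_idx[g] for g in fold_rank]))

    def cv_error(g: int, n_components: int) -> float:
        pred = np.empty(n)
        fp = _pls_fp(n_components)
        for train_idx, test_idx, fold_rank in fold_rankings:
            cols = fold_rank[:g]
            pred[test_idx] = fp(X_all[np.ix_(train_idx, cols)], y[train_idx],
                                X_all[np.ix_(test_idx, cols)])
        return float(np.mean((pred - y) ** 2))

    g_max = min(hyper.max_genes, len(ranked_genes))
    cv_by_g = {g: cv_error(g, min(hyper.max_pls_components, g)) for g in range(1, g_max + 1)}
    g_star = min(cv_by_g, key=lambda g: (cv_by_g[g], g))
    if cv_by_g[g_star] >= baseline:
        log.info("stepwise stage: no gene count beats the intercept-only baseline; empty selection")
        return [], None, 0

    selected = ranked_genes[:g_star]
    Xg = expr[selected].to_numpy(dtype=float)
    cv_by_c = {
        c: cv_error(g_star, c)
        for c in range(1, min(hyper.max_pls_components, g_star) + 1)
    }
    c_star = min(cv_by_c, key=lambda c: (cv_by_c[c], c))
    pls = _fit_pls(Xg, y, c_star)
    return selected, pls, int(pls.n_components)


@dataclass
class MarkerSet:
    """Aging markers: modality-tagged features with final regression weights."""

    table: pd.DataFrame  # columns: modality, feature, weight, rank

    @classmethod
    def from_weights(cls, weights: pd.Series) -> "MarkerSet":
        rows = [
            {"modality": mod, "feature": feat, "weight": w}
            for (mod, feat), w in weights.items()
            if w != 0
        ]
        table = pd.DataFrame(rows, columns=["modality", "feature", "weight"])
        table = table.reindex(table["weight"].abs().sort_values(ascending=False, kind="stable").index)
        table = table.reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
        return cls(table)

    @property
    def features(self) -> list[str]:
        return list(self.table["feature"])

    def genes(self, probe_gene_map: dict[str, str] | None = None) -> list[str]:
        """Marker gene symbols: expression features as-is, probes via the map."""
        out: list[str] = []
        dropped = 0
        for _, row in self.table.iterrows():
            if row["modality"] == "expression":
                out.append(row["feature"])
            elif probe_gene_map and row["feature"] in probe_gene_map:
                out.append(probe_gene_map[row["feature"]])
            else:
                dropped += 1
        if dropped:
            log.info("markers: %d methylation probe(s) without gene mapping dropped", dropped)
        return list(dict.fromkeys(out))


def fit_isap(dataset: OmicsDataset, hyper: IsapHyperparams | None = None, train_samples=None):
    """Fit the full pipeline on the training samples of a preprocessed dataset.

    Returns ``(IsapModel, MarkerSet)``.
    """
    hyper = hyper or IsapHyperparams()
    hyper.validate()
    train = dataset if train_samples is None else dataset.subset(train_samples)
    y_centered, _, age_mean = center_ages(train.ages.to_numpy())
    folds = make_folds(
        train.samples,
        tissues=train.tissues.to_numpy(),
        scheme=hyper.cv_scheme,
        k=hyper.n_folds,
        seed=hyper.seed,
    )
    meth_coefs, lasso_b, residuals, lam = fit_lasso_stage(train.meth, y_centered, hyper, folds)
    ranked = rank_genes_by_residual_correlation(train.expr, residuals)
    selected, pls, n_comp = fit_stepwise_pls_stage(train.expr, residuals, ranked, hyper, folds)

    if pls is not None:
        x_mean = pls._x_mean
        x_weights = pls.x_rotations_
        coef = pls.coef_.ravel()
        intercept = float(pls.intercept_.ravel()[0] if np.ndim(pls.intercept_) else pls.intercept_)
    else:
        x_mean = np.zeros(0)
        x_weights = np.zeros((0, 0))
        coef = np.zeros(0)
        intercept = 0.0

    model = IsapModel(
        meth_coefs=meth_coefs,
        lasso_intercept=lasso_b,
        lambda_chosen=lam,
        selected_genes=selected,
        pls_x_mean=np.asarray(x_mean, dtype=float),
        pls_x_weights=np.asarray(x_weights, dtype=float),
        pls_coef=np.asarray(coef, dtype=float),
        pls_intercept=intercept,
        n_components=n_comp,
        train_age_mean=age_mean,
    )
    markers = MarkerSet.from_weights(model.combined_weights)
    return model, markers


def predict(model: IsapModel, meth: pd.DataFrame, expr: pd.DataFrame) -> np.ndarray:
    """Apply a fitted model: train mean + stage-1 linear part + stage-2 PLS part."""
    missing = [p for p in model.meth_coefs.index if p not in meth.columns] + [
        g for g in model.selected_genes if g not in expr.columns
    ]
    if missing:
        raise KeyError(f"model features missing from input: {missing[:10]}")
    yhat = (
        model.train_age_mean
        + meth[model.meth_coefs.index].to_numpy(dtype=float) @ model.meth_coefs.to_numpy()
        + model.lasso_intercept
    )
    if model.selected_genes:
        Xe = expr[model.selected_genes].to_numpy(dtype=float)
        yhat = yhat + Xe @ model.pls_coef + model.pls_intercept
    return yhat


def predict_flat(model: IsapModel, meth: pd.DataFrame, expr: pd.DataFrame) -> np.ndarray:
    """Prediction via the flattened combined weights; must match :func:`predict`."""
    w = model.combined_weights
    yhat = np.full(len(meth), model.train_age_mean + model.combined_intercept)
    for (mod, feat), weight in w.items():
        col = meth[feat] if mod == "methylation" else expr[feat]
        yhat = yhat + weight * col.to_numpy(dtype=float)
    return yhat


def evaluate(predictions, truth, groups=None) -> pd.DataFrame:
    """Per-group regression report: SSE, Pearson r, median signed error, n.

    Mirrors the multi-tissue report layout: one row per group plus an
    ``all`` row.  Correlation is NaN when undefined (constant vector or
    n < 2).
    """
    pred = np.asarray(predictions, dtype=float)
    y = np.asarray(truth, dtype=float)
    if pred.shape != y.shape:
        raise ValueError("predictions and truth must have equal length")
    groups = np.asarray(groups) if groups is not None else np.full(len(y), "all")

    def row(label, p, t):
        err = p - t
        if len(t) >= 2 and np.std(t) > 0 and np.std(p) > 0:
            corr = float(np.corrcoef(p, t)[0, 1])
        else:
            corr = float("nan")
        return {
            "group": label,
            "residual_error": float(np.sum(err**2)),
            "correlation": corr,
            "median_error": float(np.median(err)),
            "n": int(len(t)),
        }

    rows = [row(g, pred[groups == g], y[groups == g]) for g in sorted(pd.unique(groups))]
    if len(rows) > 1 or rows[0]["group"] != "all":
        rows.append(row("all", pred, y))
    return pd.DataFrame(rows, columns=["group", "residual_error", "correlation", "median_error", "n"])


def compare_methods(dataset: OmicsDataset, train_samples, test_samples, hyper: IsapHyperparams | None = None):
    """Test-set sum of squared errors for ISAP vs single-modality Lasso baselines.

    Returns a dict method -> SSE on the held-out samples (years^2); the
    comparison behind the claim that integrating expression residual signal
    improves on methylation alone.
    """
    hyper = hyper or IsapHyperparams()
    train = dataset.subset(train_samples)
    test = dataset.subset(test_samples)
    y_tr, _, age_mean = center_ages(train.ages.to_numpy())
    y_te = test.ages.to_numpy()
    folds = make_folds(train.samples, tissues=train.tissues.to_numpy(), scheme=hyper.cv_scheme, k=hyper.n_folds, seed=hyper.seed)

    out = {}
    for name, Xtr, Xte in (
        ("lasso_methylation", train.meth, test.meth),
        ("lasso_expression", train.expr, test.expr),
    ):
        coefs, b, _, _ = fit_lasso_stage(Xtr, y_tr, hyper, folds)
        pred = age_mean + Xte[coefs.index].to_numpy() @ coefs.to_numpy() + b
        out[name] = float(np.sum((pred - y_te) ** 2))
    model, _ = fit_isap(dataset, hyper, train_samples=train_samples)
    pred = predict(model, test.meth, test.expr)
    out["isap"] = float(np.sum((pred - y_te) ** 2))
    return out
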