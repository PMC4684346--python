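"""Scoring (Pearson r, MAE, NRMSE) and the k-fold cross-validation driver.

NRMSE is ``sqrt( sum (y - yhat)^2 / sum (y - ybar)^2 )`` — 0 for perfect
prediction, exactly 1 when predicting the training mean.  Cross-validation
pools the out-of-fold predictions and scores each response once on the
pooled vectors (rather than averaging per-fold scores), matching how a
per-drug correlation over all cell lines is usually reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .costs import make_criterion
from .dataset import Dataset
from .forest import build_forest, forest_predict

CRITERION_ALIASES = {
    "rf": "rf",
    "sse": "sse",
    "vmrf": "mahalanobis",
    "mahalanobis": "mahalanobis",
    "cmrf": "copula",
    "copula": "copula",
}


def pearson_r(y: np.ndarray, yhat: np.ndarray) -> float:
    """Sample Pearson correlation; NaN (with a warning) when either side
    has zero variance."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 points")
    if np.std(y) == 0 or np.std(yhat) == 0:
        warnings.warn("zero variance; Pearson correlation undefined")
        return float("nan")
    return float(stats.pearsonr(y, yhat).statistic)


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute error."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(y - yhat)))


def nrmse(y: np.ndarray, yhat: np.ndarray, sqrt: bool = True) -> float:
    """Root of prediction SSE over the centred sum of squares of ``y``.

    ``sqrt=False`` returns the un-rooted quotient (the squared form).
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need at least 2 points")
    den = float(np.sum((y - y.mean()) ** 2))
    if den == 0:
        raise ValueError("response has zero variance; NRMSE undefined")
    q = float(np.sum((y - yhat) ** 2)) / den
    return float(np.sqrt(q)) if sqrt else q


@dataclass
class MetricsReport:
    """Per-response scores from pooled out-of-fold predictions."""

    per_response: list[dict]
    n_eval: int
    folds: int
    seed: int
    alpha_used: list[float] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    y_true: np.ndarray | None = None
    y_pred: np.ndarray | None = None

    def score(self, metric: str = "pearson_r") -> float:
        """Mean of one metric across responses (NaNs ignored)."""
        vals = [row[metric] for row in self.per_response]
        return float(np.nanmean(vals))


def score_predictions(Y: np.ndarray, Yhat: np.ndarray,
                      response_names: list[str] | None = None) -> list[dict]:
    """Per-response {pearson_r, mae, nrmse} rows for matched matrices."""
    Y = np.atleast_2d(Y)
    Yhat = np.atleast_2d(Yhat)
    names = response_names or [f"Y{k + 1}" for k in range(Y.shape[1])]
    rows = []
    for j, name in enumerate(names):
        rows.append({
            "response": name,
            "pearson_r": pearson_r(Y[:, j], Yhat[:, j]),
            "mae": mae(Y[:, j], Yhat[:, j]),
            "nrmse": nrmse(Y[:, j], Yhat[:, j]),
        })
    return rows


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffled partition of range(n) into k near-equal folds."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    if n < k:
        raise ValueError("more folds than samples")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(perm, k)
    if min(len(f) for f in folds) < 2:
        raise ValueError("a fold has fewer than 2 test rows; use smaller k")
    return folds


def _fit_predict(train: Dataset, X_test: np.ndarray, kind: str, alpha: float,
                 fp: dict, seed) -> np.ndarray:
    """Train one forest (or per-response univariate forests for 'rf')
    and predict the test rows."""
    common = dict(
        T=fp.get("T", 150), m=fp.get("m", 10), n_size=fp.get("n_size", 5),
        bootstrap_frac=fp.get("bootstrap_frac", 1.0),
        grid_resolution=fp.get("grid_resolution", 10),
        allow_negative_gain=fp.get("allow_negative_gain", True),
    )
    if kind == "rf":
        cols = []
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        for j, child in enumerate(ss.spawn(train.n_responses)):
            sub = Dataset(train.sample_ids, train.X, train.Y[:, [j]],
                          list(train.feature_names), [train.response_names[j]])
            f = build_forest(sub, "sse", seed=child, **common)
            cols.append(forest_predict(X_test, f, sub.Y)[:, 0])
        return np.column_stack(cols)
    crit = make_criterion(kind, train.Y, alpha=alpha,
                          grid_resolution=common["grid_resolution"],
                          allow_negative_gain=common["allow_negative_gain"])
    f = build_forest(train, crit, T=common["T"], m=common["m"], n_size=common["n_size"],
                     bootstrap_frac=common["bootstrap_frac"], seed=seed)
    return forest_predict(X_test, f, train.Y)


def cross_validate(
    ds: Dataset,
    k: int = 5,
    criterion: str = "copula",
    alpha_policy: float | str = 1.0,
    forest_params: dict | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Seeded k-fold cross-validation of a forest criterion.

    ``alpha_policy`` is a fixed alpha, or ``"grid"`` / ``"pareto"`` to
    re-select alpha inside each training fold (it is then fixed for all
    trees of that fold's forest).  Metrics are computed on the pooled
    out-of-fold predictions, per response.
    """
    kind = CRITERION_ALIASES.get(criterion)
    if kind is None:
        raise ValueError(f"unknown criterion {criterion!r}")
    fp = forest_params or {}
    folds = kfold_indices(ds.n, k, seed)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.spawn(2 * k)
    y_pred = np.full_like(ds.Y, np.nan, dtype=float)
    alphas: list[float] = []
    for fi, test_rows in enumerate(folds):
        train_rows = np.setdiff1d(np.arange(ds.n), test_rows)
        train = ds.subset_rows(train_rows)
        alpha = alpha_policy
        if kind == "copula" and isinstance(alpha_policy, str):
            from .alpha import select_alpha_grid, select_alpha_pareto

            if alpha_policy == "grid":
                choice = select_alpha_grid(train, forest_params=fp, seed=fold_seeds[2 * fi + 1])
            elif alpha_policy == "pareto":
                choice = select_alpha_pareto(train, forest_params=fp, seed=fold_seeds[2 * fi + 1])
            else:
                raise ValueError(f"unknown alpha policy {alpha_policy!r}")
            alpha = choice.alpha
        elif isinstance(alpha_policy, str):
            alpha = 1.0  # alpha is meaningless outside the copula criterion
        alphas.append(float(alpha))
        y_pred[test_rows] = _fit_predict(train, ds.X[test_rows], kind, float(alpha),
                                         fp, fold_seeds[2 * fi])
    per_response = score_predictions(ds.Y, y_pred, list(ds.response_names))
    return MetricsReport(
        per_response=per_response, n_eval=ds.n, folds=k, seed=seed,
        alpha_used=alphas, sample_ids=list(ds.sample_ids),
        y_true=ds.Y.copy(), y_pred=y_pred,
    )
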