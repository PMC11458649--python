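"""Leave-one-out cross-validation and evaluation statistics for the age model.

Each eye in turn is held out, the penalized regression is fitted on the
remaining N−1 eyes, and the held-out age is predicted — N fits in total. The
held-out predictions yield the headline statistics: mean absolute error (MAE)
with a 95% confidence interval and Pearson's correlation between actual and
predicted age. A final model is then refitted on all N eyes with the same
penalty-selection strategy; features whose coefficient is exactly zero are
"not selected".

Penalty selection ("lambda strategy"):

* ``"inner_cv"`` (default) — within each training fold, K-fold cross-
  validation over a log-spaced λ path picks the λ minimizing validation MSE.
  Selection happens strictly inside the training fold, so no information
  about the held-out eye leaks into its prediction. Inner fold assignment is
  derived from the sorted row identifiers, making every statistic invariant
  to the order rows arrive in.
* ``"fixed"`` — a user-supplied λ used for every fold.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFeatureError, UndefinedCorrelationError
from .lasso import (
    CohortTable,
    LassoModel,
    fit,
    fit_path_gram,
    lambda_path,
    standardize,
)

__all__ = [
    "CVResult",
    "mae_with_ci",
    "pearson",
    "choose_lambda",
    "loocv",
    "final_model",
    "coefficient_report",
    "null_loocv_mae",
]


@dataclass(frozen=True)
class CVResult:
    """Per-eye leave-one-out predictions and the derived statistics."""

    ids: tuple[str, ...]
    actual: np.ndarray
    predictions: np.ndarray
    mae: float
    mae_ci_low: float
    mae_ci_high: float
    pearson_r: float
    lambda_used: np.ndarray  # per-fold λ, aligned with ids

    def per_eye_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.ids),
                "actual_age": self.actual,
                "predicted_age": self.predictions,
                "abs_error": np.abs(self.actual - self.predictions),
                "fold_lambda": self.lambda_used,
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "n": len(self.ids),
            "mae": self.mae,
            "mae_ci_low": self.mae_ci_low,
            "mae_ci_high": self.mae_ci_high,
            "pearson_r": self.pearson_r,
            "mean_actual": float(np.mean(self.actual)),
            "sd_actual": float(np.std(self.actual, ddof=1)),
            "mean_predicted": float(np.mean(self.predictions)),
            "sd_predicted": float(np.std(self.predictions, ddof=1)),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def mae_with_ci(
    actual: np.ndarray,
    predicted: np.ndarray,
    ci_method: str = "normal",
    bootstrap_reps: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Mean absolute error and its 95% confidence interval.

    ``ci_method="normal"`` uses the large-sample normal approximation
    mae ± 1.96·sd(|e|)/√N; ``"bootstrap"`` uses the 2.5/97.5 percentiles of
    seeded nonparametric bootstrap means over the absolute errors.
    """
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have the same length")
    n = len(actual)
    if n < 2:
        raise ValueError("need at least 2 pairs for a confidence interval")
    abs_err = np.abs(actual - predicted)
    mae = float(abs_err.mean())
    if ci_method == "normal":
        half = 1.96 * float(abs_err.std(ddof=1)) / np.sqrt(n)
        return mae, mae - half, mae + half
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(bootstrap_reps, n))
        boot = abs_err[idx].mean(axis=1)
        lo, hi = np.percentile(boot, [2.5, 97.5])
        return mae, float(lo), float(hi)
    raise ValueError(f"unknown ci_method {ci_method!r}")


def pearson(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Sample Pearson correlation between actual and predicted values."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or len(actual) < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if np.ptp(actual) == 0 or np.ptp(predicted) == 0:
        raise UndefinedCorrelationError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(actual, predicted).statistic)


def _inner_fold_assignment(ids: tuple[str, ...], k: int, seed: int) -> np.ndarray:
    """Fold labels in 0..k-1 per row, derived from sorted ids (order-invariant)."""
    n = len(ids)
    order = np.argsort(np.asarray(ids, dtype=object))  # stable key: the id itself
    rng = np.random.default_rng(seed)
    shuffled = order[rng.permutation(n)]
    labels = np.empty(n, dtype=int)
    labels[shuffled] = np.arange(n) % k
    return labels


def choose_lambda(
    table: CohortTable,
    strategy: str = "inner_cv",
    fixed_lambda: float | None = None,
    alpha: float = 1.0,
    n_lambda: int = 50,
    ratio_min: float = 1e-2,
    inner_folds: int = 10,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    selection_tol: float = 1e-4,
) -> float:
    """Select the penalty weight λ for a training table.

    The inner-CV path fits only rank λ values by validation MSE, so they use
    the looser ``selection_tol``; the model actually fitted at the chosen λ
    uses the strict ``tol``.
    """
    if strategy == "fixed":
        if fixed_lambda is None:
            raise ValueError("strategy 'fixed' requires fixed_lambda")
        return float(fixed_lambda)
    if strategy != "inner_cv":
        raise ValueError(f"unknown lambda strategy {strategy!r}")
    if table.y is None:
        raise ValueError("lambda selection needs a response column")
    k = min(inner_folds, table.n)
    Xs_all, yc_all, _ = standardize(table.X, table.y, table.feature_names)
    lambdas = lambda_path(Xs_all, yc_all, n_lambda=n_lambda, ratio_min=ratio_min, alpha=alpha)
    labels = _inner_fold_assignment(table.ids, k, seed)
    sse = np.zeros(len(lambdas))
    for f in range(k):
        val = labels == f
        tr = ~val
        Xs, yc, std = standardize(table.X[tr], table.y[tr], table.feature_names)
        n_tr = int(tr.sum())
        G = Xs.T @ Xs / n_tr
        c = Xs.T @ yc / n_tr
        betas = fit_path_gram(
            G, c, lambdas, alpha=alpha, tol=max(tol, selection_tol), max_iter=max_iter
        )
        Xv = (table.X[val] - std.x_means) / std.x_sds
        preds = std.y_mean + Xv @ betas.T  # (n_val, n_lambda)
        sse += ((table.y[val][:, None] - preds) ** 2).sum(axis=0)
    # ties broken toward the larger (sparser) λ, which comes first on the path
    return float(lambdas[int(np.argmin(sse))])


def loocv(
    table: CohortTable,
    lambda_strategy: str = "inner_cv",
    fixed_lambda: float | None = None,
    alpha: float = 1.0,
    seed: int = 0,
    n_lambda: int = 50,
    ratio_min: float = 1e-2,
    inner_folds: int = 10,
    ci_method: str = "normal",
    bootstrap_reps: int = 2000,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> CVResult:
    """Leave-one-out cross-validation: N fits, one held-out prediction each."""
    if table.y is None:
        raise ValueError("LOOCV needs a response column")
    if table.n < 3:
        raise ValueError("LOOCV needs at least 3 rows")
    n = table.n
    predictions = np.empty(n)
    lambdas_used = np.empty(n)
    all_rows = np.arange(n)
    for i in range(n):
        train = table.subset(all_rows != i)
        try:
            lam = choose_lambda(
                train,
                strategy=lambda_strategy,
                fixed_lambda=fixed_lambda,
                alpha=alpha,
                n_lambda=n_lambda,
                ratio_min=ratio_min,
                inner_folds=inner_folds,
                seed=seed,
                tol=tol,
                max_iter=max_iter,
            )
            model = fit(train, lam, alpha=alpha, tol=tol, max_iter=max_iter)
        except DegenerateFeatureError as exc:
            raise DegenerateFeatureError(f"LOOCV fold {i} (held-out id {table.ids[i]}): {exc}") from exc
        predictions[i] = model.predict(table.X[i : i + 1])[0]
        lambdas_used[i] = lam
    mae, lo, hi = mae_with_ci(
        table.y, predictions, ci_method=ci_method, bootstrap_reps=bootstrap_reps, seed=seed
    )
    return CVResult(
        ids=table.ids,
        actual=table.y.copy(),
        predictions=predictions,
        mae=mae,
        mae_ci_low=lo,
        mae_ci_high=hi,
        pearson_r=pearson(table.y, predictions),
        lambda_used=lambdas_used,
    )


def null_loocv_mae(table: CohortTable) -> float:
    """MAE of the intercept-only predictor under leave-one-out (baseline)."""
    if table.y is None:
        raise ValueError("needs a response column")
    y = table.y
    n = len(y)
    preds = (y.sum() - y) / (n - 1)  # training-fold mean for each held-out row
    return float(np.abs(y - preds).mean())


def final_model(
    table: CohortTable,
    lambda_strategy: str = "inner_cv",
    fixed_lambda: float | None = None,
    alpha: float = 1.0,
    seed: int = 0,
    n_lambda: int = 50,
    ratio_min: float = 1e-2,
    inner_folds: int = 10,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> LassoModel:
    """Refit on all rows with λ chosen by the same strategy used in LOOCV."""
    lam = choose_lambda(
        table,
        strategy=lambda_strategy,
        fixed_lambda=fixed_lambda,
        alpha=alpha,
        n_lambda=n_lambda,
        ratio_min=ratio_min,
        inner_folds=inner_folds,
        seed=seed,
        tol=tol,
        max_iter=max_iter,
    )
    return fit(table, lam, alpha=alpha, tol=tol, max_iter=max_iter)


def coefficient_report(
    model: LassoModel, table: CohortTable, p_threshold: float = 0.001
) -> pd.DataFrame:
    """Per-feature report in the style of a selection table.

    One row per feature: the model coefficient on the original scale (NaN and
    ``selected=False`` — "N.S." — when the LASSO zeroed it), the marginal
    Pearson correlation of the feature with age, its two-sided p-value, and a
    flag at the study's significance threshold (default p < 0.001). The flag
    is reporting only; nothing downstream branches on p-values.
    """
    if table.y is None:
        raise ValueError("report needs a response column")
    rows = []
    for j, name in enumerate(model.feature_names):
        x = table.X[:, j]
        if np.ptp(x) == 0:
            r, p = np.nan, np.nan
        else:
            res = stats.pearsonr(x, table.y)
            r, p = float(res.statistic), float(res.pvalue)
        selected = model.beta_std[j] != 0.0
        rows.append(
            {
                "feature": name,
                "coefficient": model.beta[j] if selected else np.nan,
                "selected": selected,
                "pearson_r": r,
                "p_value": p,
                "significant": bool(p < p_threshold) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)
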