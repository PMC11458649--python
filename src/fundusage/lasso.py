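"""Penalized linear regression of age on fundus parameters, from scratch.

The model minimizes

    (1/2N) Σ_i (y_i − β0 − x_iᵀβ)²  +  λ P_α(β),
    P_α(β) = Σ_j [ (1−α)/2 β_j² + α |β_j| ],

i.e. the elastic-net family with mixing parameter α; α = 1 (the default) is
the pure LASSO, whose L1 penalty drives coefficients exactly to zero and so
performs variable selection. Optimization is cyclic coordinate descent on the
standardized design (each column mean 0, population standard deviation 1; the
response centered), with the intercept handled by centering and left
unpenalized. Coefficients are reported on both the standardized and the
original scale.

Standardization uses the population standard deviation (divisor N) to match
the 1/2N normalization of the squared loss; predictions are invariant to this
choice because the back-transformation uses the same constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._cd import _cd_gram
from .errors import DegenerateFeatureError

__all__ = [
    "CohortTable",
    "Standardization",
    "LassoModel",
    "standardize",
    "soft_threshold",
    "penalty",
    "objective",
    "lambda_max",
    "lambda_path",
    "fit",
    "fit_path_gram",
]


@dataclass(frozen=True)
class CohortTable:
    """A cohort of eyes: identifiers, the N×p feature matrix, and ages.

    ``y`` may be omitted for feature tables without the age column (e.g. the
    output of extraction before ages are joined); fitting requires it.
    """

    ids: tuple[str, ...]
    X: np.ndarray
    feature_names: tuple[str, ...]
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        n, p = X.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids for {n} rows")
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} names for {p} columns")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains missing or non-finite values")
        if self.y is not None:
            y = np.asarray(self.y, dtype=float)
            object.__setattr__(self, "y", y)
            if y.shape != (n,):
                raise ValueError("y must align with the rows of X")
            if not np.all(np.isfinite(y)):
                raise ValueError("y contains missing or non-finite values")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, rows: np.ndarray) -> "CohortTable":
        rows = np.asarray(rows)
        return CohortTable(
            ids=tuple(np.asarray(self.ids, dtype=object)[rows]),
            X=self.X[rows],
            feature_names=self.feature_names,
            y=None if self.y is None else self.y[rows],
        )


@dataclass(frozen=True)
class Standardization:
    """Column means/SDs of X and the mean of y, for scale round-trips."""

    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float


def standardize(
    X: np.ndarray, y: np.ndarray, feature_names: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, Standardization]:
    """Center/scale columns to mean 0, population SD 1; center y.

    Raises :class:`DegenerateFeatureError` naming the offending column if any
    feature is constant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population (divisor N)
    bad = np.flatnonzero(sds == 0)
    if bad.size:
        names = (
            [feature_names[j] for j in bad]
            if feature_names is not None
            else [f"column {j}" for j in bad]
        )
        raise DegenerateFeatureError(f"constant feature(s) cannot be standardized: {names}")
    Xs = (X - means) / sds
    y_mean = float(y.mean())
    return Xs, y - y_mean, Standardization(x_means=means, x_sds=sds, y_mean=y_mean)


def soft_threshold(z: float, gamma: float) -> float:
    """S(z, γ) = sign(z)·max(|z|−γ, 0); returns exactly 0.0 in the dead zone."""
    if gamma < 0:
        raise ValueError("soft-threshold parameter must be non-negative")
    mag = abs(z) - gamma
    if mag <= 0:
        return 0.0
    return mag if z > 0 else -mag


def penalty(beta: np.ndarray, alpha: float = 1.0) -> float:
    """Elastic-net penalty P_α(β) = Σ_j [(1−α)/2 β_j² + α|β_j|]."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    beta = np.asarray(beta, dtype=float)
    return float(0.5 * (1.0 - alpha) * np.sum(beta**2) + alpha * np.sum(np.abs(beta)))


def objective(
    beta0: float,
    beta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = 1.0,
) -> float:
    """The penalized least-squares objective (1/2N)·RSS + λ·P_α(β)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    resid = y - beta0 - X @ np.asarray(beta, dtype=float)
    return float(resid @ resid / (2.0 * len(y)) + lam * penalty(beta, alpha))


def lambda_max(Xs: np.ndarray, yc: np.ndarray, alpha: float = 1.0) -> float:
    """Smallest λ at which all coefficients are zero: max_j |x_jᵀy| / (N·α).

    On the standardized scale this is the KKT bound; for α = 0 there is no
    finite bound and the ridge convention max_j |x_jᵀy|/(N·0.001) is used.
    """
    corr = np.abs(Xs.T @ yc) / len(yc)
    return float(corr.max() / max(alpha, 1e-3))


def lambda_path(
    Xs: np.ndarray,
    yc: np.ndarray,
    n_lambda: int = 50,
    ratio_min: float = 1e-2,
    alpha: float = 1.0,
) -> np.ndarray:
    """Log-spaced, strictly decreasing λ sequence from λ_max to ratio_min·λ_max."""
    if n_lambda < 2:
        raise ValueError("n_lambda must be at least 2")
    if not 0.0 < ratio_min < 1.0:
        raise ValueError("ratio_min must be in (0, 1)")
    lmax = lambda_max(Xs, yc, alpha)
    return np.exp(np.linspace(math.log(lmax), math.log(ratio_min * lmax), n_lambda))


@dataclass(frozen=True)
class LassoModel:
    """A fitted penalized regression, on both scales.

    ``beta_std`` acts on standardized features with a centered response;
    (``beta0``, ``beta``) act on raw features and predict years directly.
    """

    feature_names: tuple[str, ...]
    beta0: float
    beta: np.ndarray
    beta_std: np.ndarray
    lam: float
    alpha: float
    standardization: Standardization
    n_iter: int
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + np.asarray(X, dtype=float) @ self.beta

    @property
    def selected(self) -> tuple[str, ...]:
        """Features with a nonzero coefficient (the LASSO's chosen variables)."""
        return tuple(
            name for name, b in zip(self.feature_names, self.beta_std) if b != 0.0
        )

    def to_json_dict(self) -> dict:
        s = self.standardization
        return {
            "feature_names": list(self.feature_names),
            "beta0": self.beta0,
            "beta": list(map(float, self.beta)),
            "beta_std": list(map(float, self.beta_std)),
            "lambda": self.lam,
            "alpha": self.alpha,
            "x_means": list(map(float, s.x_means)),
            "x_sds": list(map(float, s.x_sds)),
            "y_mean": s.y_mean,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json_dict(cls, d: dict) -> "LassoModel":
        return cls(
            feature_names=tuple(d["feature_names"]),
            beta0=float(d["beta0"]),
            beta=np.asarray(d["beta"], dtype=float),
            beta_std=np.asarray(d["beta_std"], dtype=float),
            lam=float(d["lambda"]),
            alpha=float(d["alpha"]),
            standardization=Standardization(
                x_means=np.asarray(d["x_means"], dtype=float),
                x_sds=np.asarray(d["x_sds"], dtype=float),
                y_mean=float(d["y_mean"]),
            ),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
        )

    @classmethod
    def from_json(cls, path) -> "LassoModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json_dict(json.load(fh))


def fit(
    table: CohortTable,
    lam: float,
    alpha: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    warm_start: np.ndarray | None = None,
) -> LassoModel:
    """Fit the penalized regression by cyclic coordinate descent.

    Convergence is declared when the largest absolute change of any
    standardized coefficient over a full sweep falls below ``tol``. A
    non-converged fit is returned (not raised) with ``converged=False``.
    """
    if table.y is None:
        raise ValueError("CohortTable has no response column to fit")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    Xs, yc, std = standardize(table.X, table.y, table.feature_names)
    n = table.n
    G = Xs.T @ Xs / n
    c = Xs.T @ yc / n
    beta_std = (
        np.zeros(table.p) if warm_start is None else np.array(warm_start, dtype=float)
    )
    n_iter, converged = _cd_gram(
        G, c, beta_std, lam * alpha, lam * (1.0 - alpha), tol, max_iter
    )
    if not converged:
        import warnings

        warnings.warn(
            f"coordinate descent did not converge in {max_iter} sweeps (lambda={lam:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    beta = beta_std / std.x_sds
    beta0 = std.y_mean - float(std.x_means @ beta)
    return LassoModel(
        feature_names=table.feature_names,
        beta0=beta0,
        beta=beta,
        beta_std=beta_std.copy(),
        lam=float(lam),
        alpha=float(alpha),
        standardization=std,
        n_iter=int(n_iter),
        converged=bool(converged),
    )


def fit_path_gram(
    G: np.ndarray,
    c: np.ndarray,
    lambdas: np.ndarray,
    alpha: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Warm-started standardized coefficient path over a decreasing λ sequence.

    Works directly on the Gram statistics of an (already standardized) design,
    which makes inner cross-validation loops cheap: the cost per fit is O(p²)
    per sweep, independent of N. Returns an (n_lambda, p) array.
    """
    p = c.shape[0]
    betas = np.empty((len(lambdas), p))
    beta = np.zeros(p)
    for k, lam in enumerate(lambdas):
        _cd_gram(G, c, beta, lam * alpha, lam * (1.0 - alpha), tol, max_iter)
        betas[k] = beta
    return betas
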