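"""Penalized linear models with an exactly specified objective.

The fitted model is v = β₀ + Σᵢ βᵢ·Pᵢ. Internally predictors are centered
and scaled to unit variance (population sd, denominator n) on the training
data, and the objective minimized in that standardized space is

    (1/(2n))·Σ(y − β₀ − Xβ)² + λ·[ α·‖β‖₁ + ((1−α)/2)·‖β‖₂² ]

with α = 1 (lasso), α = 0 (ridge), λ = 0 (OLS) — the glmnet/scikit-learn
convention, so λ magnitudes are comparable across tools and the
single-predictor closed forms hold exactly: ridge β = ρ/(1+λ) and lasso
β = sign(ρ)·max(|ρ|−λ, 0) where ρ = (1/n)Σxᵢyᵢ on standardized x, centered
y. The intercept is never penalized; reported coefficients are transformed
back to the caller's original predictor scale.

Ridge solves its normal equations in closed form via SVD — which also yields
the whole λ path from one decomposition, the workhorse of the inner
cross-validation. Lasso solves go through scikit-learn's coordinate descent,
whose objective matches the one above term for term.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "PenalizedLinearModel",
    "LambdaPath",
    "ConstantResponseError",
    "fit",
    "predict",
    "fit_with_lambda_cv",
    "default_lambda_path",
]

_PENALTIES = ("none", "ridge", "lasso")


class ConstantResponseError(ValueError):
    """The response has no variance; no model can be cross-validated on it."""


@dataclass
class PenalizedLinearModel:
    """A fitted linear model on the caller's predictor scale."""

    penalty: str
    lam: float
    intercept: float
    coefficients: pd.Series  # indexed by predictor name, original scale
    train_means: pd.Series
    train_sds: pd.Series  # population sd; constant columns recorded as 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "penalty": self.penalty,
                "lambda": self.lam,
                "intercept": self.intercept,
                "coefficients": self.coefficients.to_dict(),
                "train_means": self.train_means.to_dict(),
                "train_sds": self.train_sds.to_dict(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PenalizedLinearModel":
        d = json.loads(s)
        return cls(
            penalty=d["penalty"],
            lam=d["lambda"],
            intercept=d["intercept"],
            coefficients=pd.Series(d["coefficients"], dtype=float),
            train_means=pd.Series(d["train_means"], dtype=float),
            train_sds=pd.Series(d["train_sds"], dtype=float),
        )


@dataclass
class LambdaPath:
    """Decreasing λ grid with the inner-CV selection rule."""

    values: np.ndarray | None = None  # None: derive from the data at fit time
    selection: str = "min_cv_error"
    inner_folds: int = 10

    def __post_init__(self) -> None:
        if self.values is not None:
            v = np.asarray(self.values, float)
            if v.size < 2 or not (np.diff(v) < 0).all() or not (v > 0).all():
                raise ValueError("lambda path must be >= 2 strictly decreasing positive values")
            self.values = v
        if self.selection != "min_cv_error":
            raise ValueError("only min_cv_error selection is implemented")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    X = np.asarray(X, float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def _standardize(Xv: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns by population sd; constant columns zeroed."""
    mean = Xv.mean(axis=0)
    sd = Xv.std(axis=0)  # ddof=0
    scale = np.where(sd > 0, sd, 1.0)
    Xs = (Xv - mean) / scale
    Xs[:, sd == 0] = 0.0  # constant columns carry no signal; coefficient 0
    return Xs, mean, sd


def _ridge_path_std(Xs: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Standardized-space ridge solutions for every λ, via one SVD.

    Minimizes (1/(2n))‖yc − Xs β‖² + (λ/2)‖β‖²; solution
    β(λ) = V·diag(s/n / (s²/n + λ))·Uᵀ yc. Returns (p, len(lambdas)).
    """
    n = Xs.shape[0]
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    uty = U.T @ yc
    # shape (r, L): filter factors per singular value per lambda
    fac = (s / n)[:, None] / ((s**2 / n)[:, None] + lambdas[None, :])
    return Vt.T @ (fac * uty[:, None])


def _solve_std(Xs: np.ndarray, yc: np.ndarray, penalty: str, lam: float) -> np.ndarray:
    """Minimizer of the stated objective in standardized space."""
    n, p = Xs.shape
    if penalty == "none" or lam == 0:
        beta, _, rank, _ = np.linalg.lstsq(Xs, yc, rcond=None)
        if penalty == "none":
            active = (Xs != 0).any(axis=0).sum()
            if rank < active:
                raise np.linalg.LinAlgError(
                    "rank-deficient design: ordinary least squares is not identified"
                )
        return beta
    if penalty == "ridge":
        return _ridge_path_std(Xs, yc, np.array([lam]))[:, 0]
    if penalty == "lasso":
        est = Lasso(alpha=lam, fit_intercept=False, tol=1e-12, max_iter=500_000)
        est.fit(Xs, yc)
        return est.coef_.astype(float)
    raise ValueError(f"unknown penalty {penalty!r}; expected one of {_PENALTIES}")


def fit(X, y, penalty: str = "none", lam: float = 0.0) -> PenalizedLinearModel:
    """Fit the model at a fixed λ.

    X: n_conditions × n_predictors table (DataFrame or array); y: response.
    Standardization is internal; coefficients come back on the original
    predictor scale and the intercept absorbs the centering, so
    ``predict`` works directly on untransformed predictors.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, float).ravel()
    if penalty not in _PENALTIES:
        raise ValueError(f"unknown penalty {penalty!r}; expected one of {_PENALTIES}")
    if len(Xf) != y.size:
        raise ValueError("X and y disagree on the number of conditions")
    if len(Xf) < 3:
        raise ValueError("need at least 3 conditions to fit")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Xv = Xf.to_numpy()
    if np.isnan(Xv).any() or np.isnan(y).any():
        raise ValueError("NaN in predictors or response")

    Xs, mean, sd = _standardize(Xv)
    ybar = float(y.mean())
    beta_std = _solve_std(Xs, y - ybar, penalty, float(lam))

    scale = np.where(sd > 0, sd, 1.0)
    beta = beta_std / scale
    beta[sd == 0] = 0.0
    intercept = ybar - float(beta @ mean)
    return PenalizedLinearModel(
        penalty=penalty,
        lam=float(lam),
        intercept=intercept,
        coefficients=pd.Series(beta, index=Xf.columns),
        train_means=pd.Series(mean, index=Xf.columns),
        train_sds=pd.Series(sd, index=Xf.columns),
    )


def predict(model: PenalizedLinearModel, X_new) -> np.ndarray:
    """β₀ + X_new·β on the original scale; requires the training predictors."""
    Xf = _as_frame(X_new)
    missing = [c for c in model.coefficients.index if c not in Xf.columns]
    if missing:
        raise ValueError(f"predictors missing from X_new: {missing}")
    Xv = Xf[list(model.coefficients.index)].to_numpy()
    return model.intercept + Xv @ model.coefficients.to_numpy()


def default_lambda_path(Xs: np.ndarray, yc: np.ndarray, n_values: int = 100) -> np.ndarray:
    """λ grid from λ_max down to λ_max·10⁻⁴, log-spaced.

    λ_max = max|Xsᵀyc|/n is the smallest λ at which the lasso solution is
    entirely zero; ridge shares the same scaffold.
    """
    n = Xs.shape[0]
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / n)
    if lam_max <= 0:  # response orthogonal to every predictor
        lam_max = 1.0
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), n_values)


def fit_with_lambda_cv(
    X,
    y,
    penalty: str,
    path: LambdaPath | None = None,
    seed: int = 0,
) -> tuple[PenalizedLinearModel, float]:
    """Choose λ by inner k-fold CV (minimum mean squared error), then refit.

    The whole path is evaluated per inner fold — for ridge from one SVD per
    fold, for lasso with scikit-learn's warm-started path. Fold
    standardization happens inside each inner training split, so no
    information from an inner validation set leaks into λ selection. Ties on
    the error curve resolve to the largest (most regularized) λ.
    """
    Xf = _as_frame(X)
    y = np.asarray(y, float).ravel()
    if penalty not in ("ridge", "lasso"):
        raise ValueError("lambda CV applies to ridge or lasso only")
    n = len(Xf)
    if n < 4:
        raise ValueError("need at least 4 conditions for inner cross-validation")
    if np.ptp(y) == 0:
        raise ConstantResponseError("constant response")
    path = path or LambdaPath()

    Xv = Xf.to_numpy()
    if path.values is None:
        Xs_all, _, _ = _standardize(Xv)
        lambdas = default_lambda_path(Xs_all, y - y.mean())
    else:
        lambdas = path.values

    n_folds = min(path.inner_folds, n)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(seed) % (2**32 - 1))
    sse = np.zeros(lambdas.size)
    for tr, va in kf.split(Xv):
        Xs, mean, sd = _standardize(Xv[tr])
        ybar = y[tr].mean()
        yc = y[tr] - ybar
        scale = np.where(sd > 0, sd, 1.0)
        Xva = (Xv[va] - mean) / scale
        Xva[:, sd == 0] = 0.0
        if penalty == "ridge":
            B = _ridge_path_std(Xs, yc, lambdas)  # (p, L)
        else:
            _, B, _ = lasso_path(Xs, yc, alphas=lambdas, tol=1e-8, max_iter=100_000)
        preds = ybar + Xva @ B  # (n_va, L)
        sse += ((preds - y[va][:, None]) ** 2).sum(axis=0)
    best = int(np.argmin(sse / n))  # first minimum = largest lambda on ties
    lam = float(lambdas[best])
    return fit(Xf, y, penalty=penalty, lam=lam), lam
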