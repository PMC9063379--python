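"""Regression models linking image features to chlorophyll content.

Two model families are fitted on the fused per-plant feature table:

* per-feature multiple linear regression,
      model a:  Chl = a0 + a1*X + a2*DAS
      model b:  Chl = b0 + b1*X + b2*DAS + b3*SLW
  compared by the Gaussian AIC = n*ln(RSS/n) + 2k (k counts the fitted
  coefficients plus the error variance); and

* fused partial least squares regression (PLSR, NIPALS with deflation of
  the predictors only; predictors standardized, response centered), with
  the component count chosen by stratified fivefold cross-validation at the
  minimum mean squared error, and predictors ranked by the absolute value
  of their standardized coefficients (supporting "drop the least important
  and refit", e.g. hue reduction).

Models are scored by R^2 (squared Pearson correlation of measured vs
predicted), RMSE, and RPD = SD(measured)/RMSE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateMetricError,
    SingularDesignError,
    ZeroVarianceError,
)

#: default calibration fraction of the 80/20 split
DEFAULT_SPLIT_FRAC = 0.8
#: default number of cross-validation folds
DEFAULT_FOLDS = 5

STRATUM_COLUMNS = ("genotype", "water", "nutrient")


# ---------------------------------------------------------------------------
# Stratified split and folds
# ---------------------------------------------------------------------------


def _stratum_keys(table: pd.DataFrame):
    cols = [c for c in STRATUM_COLUMNS if c in table.columns]
    if not cols:
        return pd.Series(["all"] * len(table), index=table.index)
    return table[cols].astype(str).agg("|".join, axis=1)


def split_calibration_validation(table: pd.DataFrame, frac: float = DEFAULT_SPLIT_FRAC,
                                 seed: int = 0):
    """Split rows into calibration/validation, stratified by
    genotype x water x nutrient, deterministically for a seed.

    Within each stratum the calibration count is round(frac * n). Strata
    with fewer than 2 rows are assigned wholly to calibration with a
    warning.
    """
    rng = np.random.default_rng(seed)
    strata = _stratum_keys(table)
    cal_idx, val_idx = [], []
    for key in sorted(strata.unique()):
        members = table.index[strata == key].to_numpy()
        if members.size < 2:
            warnings.warn(
                f"stratum {key!r} has fewer than 2 rows; assigned to calibration",
                stacklevel=2,
            )
            cal_idx.extend(members.tolist())
            continue
        perm = rng.permutation(members)
        n_cal = int(round(frac * members.size))
        cal_idx.extend(perm[:n_cal].tolist())
        val_idx.extend(perm[n_cal:].tolist())
    return table.loc[sorted(cal_idx)], table.loc[sorted(val_idx)]


def stratified_folds(table: pd.DataFrame, k_folds: int = DEFAULT_FOLDS,
                     seed: int = 0) -> np.ndarray:
    """Fold label (0..k-1) per row, balanced within each stratum."""
    if len(table) < k_folds:
        raise ValueError(f"need at least {k_folds} rows for {k_folds} folds")
    rng = np.random.default_rng(seed)
    strata = _stratum_keys(table)
    labels = pd.Series(-1, index=table.index, dtype=int)
    offset = 0
    for key in sorted(strata.unique()):
        members = table.index[strata == key].to_numpy()
        perm = rng.permutation(members)
        for j, idx in enumerate(perm):
            labels.loc[idx] = (offset + j) % k_folds
        offset += members.size
    return labels.to_numpy()


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


@dataclass
class EvalMetrics:
    """R^2, RMSE and RPD between measured and predicted chlorophyll."""

    r2: float
    rmse: float
    rpd: float
    sd: float
    n: int
    r2_ss: float  # 1 - RSS/TSS, reported alongside the correlation-based R^2

    def as_dict(self, prefix: str = "") -> dict:
        return {f"{prefix}r2": self.r2, f"{prefix}rmse": self.rmse,
                f"{prefix}rpd": self.rpd}


def evaluate(y_true, y_pred) -> EvalMetrics:
    """Score predictions: R^2 (squared Pearson correlation), RMSE, RPD.

    RPD = SD(y_true)/RMSE with the sample standard deviation (ddof=1);
    perfect predictions give RMSE 0 and an infinite RPD.
    """
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("y_true and y_pred must be equal-length 1-D with n >= 2")
    sd = float(np.std(y, ddof=1))
    if sd == 0:
        raise DegenerateMetricError("constant reference values: R^2 and RPD undefined")
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.std(yhat) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(y, yhat)[0, 1] ** 2)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2_ss = float(1.0 - np.sum(resid**2) / tss)
    rpd = float("inf") if rmse == 0 else sd / rmse
    return EvalMetrics(r2=r2, rmse=rmse, rpd=rpd, sd=sd, n=y.size, r2_ss=r2_ss)


# ---------------------------------------------------------------------------
# Multiple linear regression and AIC
# ---------------------------------------------------------------------------


@dataclass
class LinearModelFit:
    """OLS fit of Chl on {X, DAS} (formula a) or {X, DAS, SLW} (formula b)."""

    predictor: str
    formula: str  # "a" (without SLW) or "b" (with SLW)
    terms: list
    coefficients: np.ndarray  # intercept first, then terms
    r2: float
    rss: float
    aic: float
    n: int

    @property
    def k(self) -> int:
        """Fitted parameter count for AIC: coefficients + error variance."""
        return len(self.coefficients) + 1

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = np.column_stack([np.ones(len(table))] +
                            [table[t].to_numpy(float) for t in self.terms])
        return X @ self.coefficients


def gaussian_aic(rss: float, n: int, n_coefficients: int) -> float:
    """AIC under a Gaussian likelihood: n*ln(RSS/n) + 2k, k = coefficients + 1.

    RSS = 0 is degenerate and returns -inf (flagged, not an error): the
    criterion is used only for ranking.
    """
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    k = n_coefficients + 1
    if rss == 0:
        return float("-inf")
    return float(n * np.log(rss / n) + 2 * k)


def aic(fit: LinearModelFit, n: int | None = None) -> float:
    """AIC of a fitted linear model (recomputed from its RSS)."""
    return gaussian_aic(fit.rss, fit.n if n is None else n, len(fit.coefficients))


def fit_mlr(table: pd.DataFrame, predictor: str, include_slw: bool = False,
            response: str = "Chl") -> LinearModelFit:
    """Fit Chl = a0 + a1*X + a2*DAS (+ a3*SLW) by ordinary least squares."""
    terms = [predictor, "DAS"] + (["SLW"] if include_slw else [])
    y = table[response].to_numpy(float)
    X = np.column_stack([np.ones(len(table))] +
                        [table[t].to_numpy(float) for t in terms])
    n, p = X.shape
    if n <= p:
        raise SingularDesignError(f"need more than {p} rows to fit {p} coefficients")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise SingularDesignError(
            f"design matrix for terms {terms} is rank deficient (rank {rank} < {p})"
        )
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return LinearModelFit(
        predictor=predictor, formula="b" if include_slw else "a",
        terms=terms, coefficients=coef, r2=float(r2), rss=rss,
        aic=gaussian_aic(rss, n, p), n=n,
    )


# ---------------------------------------------------------------------------
# PLSR (NIPALS)
# ---------------------------------------------------------------------------


@dataclass
class PLSRFit:
    """Fitted PLSR model mapped back to the original predictor scale."""

    predictors: list
    n_components: int
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    coefficients: np.ndarray       # original predictor scale
    intercept: float
    std_coefficients: np.ndarray   # standardized-predictor scale
    cv_mse: np.ndarray | None = None   # mean CV MSE per candidate count
    cv_predictions: np.ndarray | None = None
    cv_metrics: EvalMetrics | None = None
    importance: list = field(default_factory=list)

    def predict(self, table) -> np.ndarray:
        if isinstance(table, pd.DataFrame):
            X = table[self.predictors].to_numpy(float)
        else:
            X = np.asarray(table, dtype=float)
        return self.intercept + X @ self.coefficients


def _design_matrix(table: pd.DataFrame, predictors, response: str):
    X = table[list(predictors)].to_numpy(float)
    y = table[response].to_numpy(float)
    return X, y


def _standardize(X: np.ndarray, predictors):
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0, ddof=1)
    for j, name in enumerate(predictors):
        # tolerance catches constant columns whose float std is ~1e-16
        if x_std[j] <= 1e-12 * max(1.0, abs(x_mean[j])):
            raise ZeroVarianceError(f"predictor {name!r} has zero variance")
    return (X - x_mean) / x_std, x_mean, x_std


def _nipals(Xs: np.ndarray, yc: np.ndarray, n_components: int):
    """PLS1 NIPALS: weights/loadings with deflation of the predictors only."""
    n, p = Xs.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    Xa = Xs.copy()
    actual = 0
    for a in range(n_components):
        w = Xa.T @ yc
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            break
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        P[:, a] = Xa.T @ t / tt
        q[a] = float(yc @ t) / tt
        W[:, a] = w
        Xa = Xa - np.outer(t, P[:, a])
        actual += 1
    if actual == 0:
        raise ZeroVarianceError("response carries no covariance with the predictors")
    W, P, q = W[:, :actual], P[:, :actual], q[:actual]
    B = W @ np.linalg.solve(P.T @ W, np.eye(actual)) @ q
    return B, actual


def fit_plsr(table: pd.DataFrame, predictors, n_components: int,
             response: str = "Chl") -> PLSRFit:
    """Fit PLSR of the response on the named predictors.

    Predictors are standardized and the response centered; coefficients are
    mapped back to the original scale. ``n_components`` may be reduced if
    the NIPALS recursion exhausts the predictor space early.
    """
    predictors = list(predictors)
    if not 1 <= n_components <= len(predictors):
        raise ValueError("n_components must be in [1, number of predictors]")
    X, y = _design_matrix(table, predictors, response)
    Xs, x_mean, x_std = _standardize(X, predictors)
    y_mean = float(y.mean())
    B, actual = _nipals(Xs, y - y_mean, n_components)
    coef = B / x_std
    intercept = y_mean - float(x_mean @ coef)
    fit = PLSRFit(
        predictors=predictors, n_components=actual,
        x_mean=x_mean, x_std=x_std, y_mean=y_mean,
        coefficients=coef, intercept=intercept, std_coefficients=B,
    )
    fit.importance = importance_ranking(fit)
    return fit


def importance_ranking(fit: PLSRFit) -> list:
    """Predictors ordered by descending |standardized coefficient|."""
    order = np.argsort(-np.abs(fit.std_coefficients), kind="stable")
    return [fit.predictors[j] for j in order]


def cross_validate_plsr(table: pd.DataFrame, predictors, k_folds: int = DEFAULT_FOLDS,
                        seed: int = 0, max_components: int | None = None,
                        response: str = "Chl") -> PLSRFit:
    """Select the PLSR component count by stratified k-fold cross-validation.

    The candidate counts are 1..min(p, n_train - 1); the count minimizing
    the mean CV MSE is selected (ties to the smaller count) and the final
    model is refit on all supplied rows at that count. The fit carries the
    full CV curve and the out-of-fold predictions at the selected count.
    """
    predictors = list(predictors)
    folds = stratified_folds(table, k_folds, seed)
    n = len(table)
    p = len(predictors)
    cap = min(p, n - max(np.bincount(folds, minlength=k_folds)) - 1)
    a_max = min(max_components or p, max(cap, 1))
    candidates = range(1, a_max + 1)
    preds = np.zeros((a_max, n))
    for fold in range(k_folds):
        test = folds == fold
        train_table = table.loc[~test]
        X_test = table.loc[test, predictors].to_numpy(float)
        for a in candidates:
            sub = fit_plsr(train_table, predictors, a, response=response)
            preds[a - 1, test] = sub.predict(X_test)
    y = table[response].to_numpy(float)
    cv_mse = np.mean((preds - y[None, :]) ** 2, axis=1)
    best = int(np.argmin(cv_mse)) + 1
    fit = fit_plsr(table, predictors, best, response=response)
    fit.cv_mse = cv_mse
    fit.cv_predictions = preds[best - 1]
    fit.cv_metrics = evaluate(y, preds[best - 1])
    return fit
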