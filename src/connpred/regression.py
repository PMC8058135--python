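"""Elastic-net family regression with standardization, metrics, and BIC.

The fitted objective is

    (1/2n) * sum_i (y_i - b0 - z_i^T beta)^2
        + lambda * sum_j ( (1-alpha)/2 * beta_j^2 + alpha * |beta_j| )

with an unpenalized intercept, exactly scikit-learn's ``ElasticNet``
parameterization with ``alpha=lambda`` and ``l1_ratio=alpha``; the
coordinate-descent solver is reused and solutions are verified against
the KKT conditions in the test suite.  ``alpha`` is restricted to (0, 1]:
ridge is approached with alpha ~ 0.001 rather than included exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from .errors import ConfigError, DomainError, ShapeError


@dataclass(frozen=True)
class Standardizer:
    """Column means and standard deviations estimated on a training sample."""

    means: np.ndarray
    sds: np.ndarray
    constant_columns: np.ndarray  # bool flags; their sd was reset to 1

    def apply(self, F: np.ndarray) -> np.ndarray:
        F = np.asarray(F, dtype=float)
        if F.ndim == 1:
            F = F[None, :]
        if F.shape[1] != self.means.size:
            raise ShapeError(
                f"{F.shape[1]} columns, standardizer expects {self.means.size}"
            )
        return (F - self.means) / self.sds

    @classmethod
    def identity(cls, k: int) -> "Standardizer":
        return cls(np.zeros(k), np.ones(k), np.zeros(k, dtype=bool))


@dataclass(frozen=True)
class RegressionModel:
    beta: np.ndarray
    intercept: float
    lam: float
    alpha: float
    nonzero_count: int
    standardizer: Standardizer
    objective: float
    converged: bool = True


def standardize(
    F_train: np.ndarray, F_apply: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, Standardizer]:
    """Zero-mean unit-sd columns on training rows; apply-set uses training stats.

    Sample standard deviation (ddof=1).  Constant columns get sd 1 and are
    flagged rather than producing NaN.
    """
    F_train = np.asarray(F_train, dtype=float)
    if F_train.ndim != 2 or F_train.shape[0] < 2:
        raise ConfigError("standardize needs at least 2 training rows")
    means = F_train.mean(axis=0)
    sds = F_train.std(axis=0, ddof=1)
    constant = sds == 0
    sds = np.where(constant, 1.0, sds)
    std = Standardizer(means=means, sds=sds, constant_columns=constant)
    Z_train = std.apply(F_train)
    Z_apply = std.apply(F_apply) if F_apply is not None else None
    return Z_train, Z_apply, std


def enet_objective(
    Z: np.ndarray, y: np.ndarray, beta: np.ndarray, intercept: float,
    lam: float, alpha: float,
) -> float:
    """Direct evaluation of the penalized least-squares objective."""
    n = len(y)
    resid = y - intercept - Z @ beta
    penalty = lam * np.sum(0.5 * (1 - alpha) * beta**2 + alpha * np.abs(beta))
    return float(0.5 / n * np.sum(resid**2) + penalty)


def fit_enet(
    Z: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float,
    *,
    standardizer: Standardizer | None = None,
    max_iter: int = 50_000,
    tol: float = 1e-10,
) -> RegressionModel:
    """Fit one elastic-net solution at fixed (lambda, alpha).

    ``Z`` is assumed already standardized; pass the fitted
    :class:`Standardizer` so that :func:`predict` can be applied to raw
    features.  Non-zeros are exact solver zeros, no thresholding.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if Z.shape[0] != y.size:
        raise ShapeError(f"{Z.shape[0]} rows of Z but {y.size} targets")
    if not (0 < alpha <= 1):
        raise ConfigError(f"alpha must be in (0, 1], got {alpha}")
    if lam < 0:
        raise ConfigError(f"lambda must be >= 0, got {lam}")

    if lam == 0:
        beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones_like(y), Z]), y, rcond=None
        )
        intercept, beta = float(beta[0]), beta[1:]
        converged = True
    else:
        est = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True,
            max_iter=max_iter, tol=tol,
        )
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(Z, y)
            for w in caught:
                if issubclass(w.category, ConvergenceWarning):
                    converged = False
                    warnings.warn(
                        f"elastic net did not fully converge: {w.message}",
                        stacklevel=2,
                    )
        beta = np.asarray(est.coef_, dtype=float)
        intercept = float(est.intercept_)

    if standardizer is None:
        standardizer = Standardizer.identity(Z.shape[1])
    return RegressionModel(
        beta=beta,
        intercept=intercept,
        lam=float(lam),
        alpha=float(alpha),
        nonzero_count=int(np.count_nonzero(beta)),
        standardizer=standardizer,
        objective=enet_objective(Z, y, beta, intercept, lam, alpha),
        converged=converged,
    )


def predict(model: RegressionModel, F_new: np.ndarray) -> np.ndarray:
    """Predict scores for raw (unstandardized) feature rows."""
    Z = model.standardizer.apply(F_new)
    if Z.shape[1] != model.beta.size:
        raise ShapeError(f"{Z.shape[1]} features, model has {model.beta.size}")
    return model.intercept + Z @ model.beta


def kkt_violation(
    Z: np.ndarray, y: np.ndarray, model: RegressionModel
) -> float:
    """Maximum violation of the elastic-net subgradient conditions.

    For each coefficient j the stationarity condition is
    ``g_j + lam*(1-alpha)*beta_j + lam*alpha*s_j = 0`` with
    ``g_j = -(1/n) z_j^T r`` and ``s_j`` a subgradient of ``|.|``.
    Returns the largest absolute violation over coefficients plus the
    intercept optimality residual.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    r = y - model.intercept - Z @ model.beta
    g = -(Z.T @ r) / n
    lam, alpha, beta = model.lam, model.alpha, model.beta
    viol = np.empty_like(beta)
    for j in range(beta.size):
        core = g[j] + lam * (1 - alpha) * beta[j]
        if beta[j] != 0:
            viol[j] = abs(core + lam * alpha * np.sign(beta[j]))
        else:
            viol[j] = max(0.0, abs(core) - lam * alpha)
    intercept_viol = abs(r.mean())
    return float(max(viol.max(initial=0.0), intercept_viol))


def r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot; may be negative."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ShapeError("y and y_hat must have equal length")
    if y.size < 2:
        raise ConfigError("need at least 2 observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("y has zero variance; R^2 undefined")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


def mean_squared_error(y: np.ndarray, y_hat: np.ndarray) -> float:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ShapeError("y and y_hat must have equal length")
    return float(np.mean((y - y_hat) ** 2))


def bic(y: np.ndarray, y_hat: np.ndarray, nonzero_count: int, n: int | None = None) -> float:
    """Gaussian BIC counting only the non-zero coefficients.

    ``n*ln(RSS/n) + q*ln(n)`` with ``q = nonzero_count`` (intercept and
    noise variance excluded from q).  Lower is better.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if n is None:
        n = y.size
    if n <= nonzero_count:
        raise ConfigError(f"need n > nonzero_count, got n={n}, q={nonzero_count}")
    rss = float(np.sum((y - y_hat) ** 2))
    if rss == 0:
        warnings.warn("RSS is exactly zero; BIC is -inf", stacklevel=2)
        return float("-inf")
    return n * float(np.log(rss / n)) + nonzero_count * float(np.log(n))


def save_regression_model(model: RegressionModel, path) -> None:
    """JSON dump with an embedded per-feature coefficient table."""
    import json

    payload = {
        "intercept": model.intercept,
        "lambda": model.lam,
        "alpha": model.alpha,
        "nonzero_count": model.nonzero_count,
        "objective": model.objective,
        "converged": model.converged,
        "beta": model.beta.tolist(),
        "standardizer": {
            "means": model.standardizer.means.tolist(),
            "sds": model.standardizer.sds.tolist(),
            "constant_columns": model.standardizer.constant_columns.tolist(),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_regression_model(path) -> RegressionModel:
    import json

    with open(path) as fh:
        d = json.load(fh)
    std = Standardizer(
        means=np.asarray(d["standardizer"]["means"], dtype=float),
        sds=np.asarray(d["standardizer"]["sds"], dtype=float),
        constant_columns=np.asarray(d["standardizer"]["constant_columns"], dtype=bool),
    )
    return RegressionModel(
        beta=np.asarray(d["beta"], dtype=float),
        intercept=float(d["intercept"]),
        lam=float(d["lambda"]),
        alpha=float(d["alpha"]),
        nonzero_count=int(d["nonzero_count"]),
        standardizer=std,
        objective=float(d["objective"]),
        converged=bool(d["converged"]),
    )
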