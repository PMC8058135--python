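"""Leave-one-out and nested leave-one-out hyperparameter selection.

The grid spans (k, lambda, alpha): number of extracted features, penalty
strength, and L1/L2 mix.  Plain LOO pools the n held-out predictions per
grid combination and picks the combination with the lowest pooled MSE
(with k constrained to at most n).  Nested LOO selects a combination
inside each outer training fold, predicts the outer subject with it, and
aggregates the n fold-wise selections into one final combination by mean,
median, or mode, snapped back to the grid.

The coordinate-descent path solver from scikit-learn (``enet_path``) is
used for all inner fits; standardization is computed on training rows only
(leakage-safe default) with a full-sample mode behind a flag.
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import enet_path

from .errors import ConfigError, ShapeError
from .regression import (
    RegressionModel,
    bic,
    fit_enet,
    mean_squared_error,
    predict,
    r_squared,
    standardize,
)

DEFAULT_ALPHAS = (0.001, 0.25, 0.5, 0.75, 1.0)


def default_lambda_grid() -> np.ndarray:
    """100 penalty strengths, logarithmically spaced between 1e-5 and 1e5."""
    return np.logspace(-5, 5, 100)


@dataclass(frozen=True)
class HyperGrid:
    """Search grid over (k, lambda, alpha)."""

    k_values: tuple[int, ...] = tuple(range(10, 96, 5))
    lambda_values: tuple[float, ...] = tuple(default_lambda_grid())
    alpha_values: tuple[float, ...] = DEFAULT_ALPHAS

    def __post_init__(self) -> None:
        for name, vals in (
            ("k_values", self.k_values),
            ("lambda_values", self.lambda_values),
            ("alpha_values", self.alpha_values),
        ):
            arr = np.asarray(vals, dtype=float)
            if arr.size == 0:
                raise ConfigError(f"{name} is empty")
            if (arr <= 0).any():
                raise ConfigError(f"{name} must be strictly positive")
            if not np.all(np.diff(arr) > 0):
                raise ConfigError(f"{name} must be sorted ascending without duplicates")
        for a in self.alpha_values:
            if not (0 < a <= 1):
                raise ConfigError(f"alpha values must lie in (0, 1], got {a}")

    def admissible_k(self, n: int) -> tuple[int, ...]:
        """k values usable with n subjects (models with k > n are excluded)."""
        return tuple(k for k in self.k_values if k <= n)


@dataclass(frozen=True)
class CVResult:
    """Outcome of a cross-validated grid search."""

    scheme: str                              # "loo" or "nested_loo"
    aggregation: str                         # "none", "mean", "median", "mode"
    best_hyperparams: tuple[int, float, float]
    predictions: np.ndarray                  # headline pooled held-out predictions
    y: np.ndarray
    r2: float
    mse: float
    bic: float
    nonzero_count: int
    final_model: RegressionModel
    final_k: int
    fold_selections: tuple[tuple[int, float, float], ...] | None = None
    surfaces: dict = field(default_factory=dict)

    @property
    def squared_residuals(self) -> np.ndarray:
        return (self.y - self.predictions) ** 2


def _path_coefs(
    Z: np.ndarray, y_centered: np.ndarray, alpha: float, lambdas: np.ndarray,
    tol: float, max_iter: int,
) -> np.ndarray:
    """Elastic-net coefficient path; returns (k, n_lambdas) aligned to
    ascending ``lambdas``."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = enet_path(
            Z, y_centered, l1_ratio=alpha, alphas=lambdas[::-1],
            tol=tol, max_iter=max_iter,
        )
    return coefs[:, ::-1]


def _loo_prediction_cube(
    F: np.ndarray, y: np.ndarray, lambdas: np.ndarray, alphas: Sequence[float],
    *, standardize_scope: str, tol: float, max_iter: int,
) -> np.ndarray:
    """LOO predictions for every (fold, alpha, lambda) at one k."""
    n = len(y)
    preds = np.empty((n, len(alphas), len(lambdas)))
    if standardize_scope == "full":
        Z_full, _, std_full = standardize(F)
    for i in range(n):
        train = np.arange(n) != i
        if standardize_scope == "full":
            Ztr, Zte = Z_full[train], Z_full[i : i + 1]
        else:
            Ztr, Zte, _ = standardize(F[train], F[i : i + 1])
        ytr = y[train]
        ym = ytr.mean()
        for ai, alpha in enumerate(alphas):
            coefs = _path_coefs(Ztr, ytr - ym, alpha, lambdas, tol, max_iter)
            preds[i, ai, :] = ym + (Zte @ coefs).ravel()
    return preds


def _grid_search(
    features_by_k: Mapping[int, np.ndarray],
    y: np.ndarray,
    grid: HyperGrid,
    *,
    standardize_scope: str,
    tol: float,
    max_iter: int,
) -> tuple[tuple[int, float, float], np.ndarray]:
    """Best (k, lambda, alpha) by pooled LOO MSE, and its prediction vector.

    Ties broken toward smallest k, then largest lambda, then largest alpha
    (maximum parsimony); enforced by iteration order with strict improvement.
    """
    n = len(y)
    lambdas = np.asarray(grid.lambda_values, dtype=float)
    ks = [k for k in grid.admissible_k(n) if k in features_by_k]
    if not ks:
        raise ConfigError(
            f"no admissible k values (n={n}, grid k={grid.k_values})"
        )
    best_mse = np.inf
    best_combo: tuple[int, float, float] | None = None
    best_preds: np.ndarray | None = None
    for k in sorted(ks):
        F = np.asarray(features_by_k[k], dtype=float)
        if F.shape != (n, k):
            raise ShapeError(f"features for k={k} have shape {F.shape}, expected {(n, k)}")
        cube = _loo_prediction_cube(
            F, y, lambdas, grid.alpha_values,
            standardize_scope=standardize_scope, tol=tol, max_iter=max_iter,
        )
        mse_surface = np.mean((cube - y[:, None, None]) ** 2, axis=0)
        for ai in range(len(grid.alpha_values) - 1, -1, -1):
            for li in range(len(lambdas) - 1, -1, -1):
                if mse_surface[ai, li] < best_mse:
                    best_mse = float(mse_surface[ai, li])
                    best_combo = (k, float(lambdas[li]), float(grid.alpha_values[ai]))
                    best_preds = cube[:, ai, li].copy()
    return best_combo, best_preds


def _refit_full(
    features_by_k: Mapping[int, np.ndarray],
    y: np.ndarray,
    combo: tuple[int, float, float],
) -> RegressionModel:
    k, lam, alpha = combo
    Z, _, std = standardize(np.asarray(features_by_k[k], dtype=float))
    return fit_enet(Z, y, lam, alpha, standardizer=std)


def _pooled_metrics(y: np.ndarray, preds: np.ndarray, q: int) -> tuple[float, float, float]:
    r2 = r_squared(y, preds)
    mse = mean_squared_error(y, preds)
    try:
        b = bic(y, preds, q)
    except ConfigError:
        b = float("nan")
    return r2, mse, b


def loo_select(
    features_by_k: Mapping[int, np.ndarray],
    y: np.ndarray,
    grid: HyperGrid,
    *,
    standardize_scope: str = "train",
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> CVResult:
    """Plain LOO grid search: pooled-MSE-optimal combination, refit on all n."""
    y = np.asarray(y, dtype=float).ravel()
    if len(y) < 3:
        raise ConfigError("need at least 3 scored subjects")
    combo, preds = _grid_search(
        features_by_k, y, grid,
        standardize_scope=standardize_scope, tol=tol, max_iter=max_iter,
    )
    final = _refit_full(features_by_k, y, combo)
    r2, mse, b = _pooled_metrics(y, preds, final.nonzero_count)
    return CVResult(
        scheme="loo", aggregation="none", best_hyperparams=combo,
        predictions=preds, y=y, r2=r2, mse=mse, bic=b,
        nonzero_count=final.nonzero_count, final_model=final, final_k=combo[0],
    )


def nested_loo_select(
    features_by_k: Mapping[int, np.ndarray],
    y: np.ndarray,
    grid: HyperGrid,
    aggregation: str = "median",
    *,
    standardize_scope: str = "train",
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> CVResult:
    """Nested LOO: per-fold inner selection, outer prediction, aggregation.

    Two performance surfaces are reported: ``surfaces['outer']`` pools the
    outer-fold predictions made with fold-specific hyperparameters (the
    conservative headline, also used for the top-level metrics), and
    ``surfaces['aggregated']`` re-runs a plain LOO at the single aggregated
    combination.
    """
    if aggregation not in ("mean", "median", "mode"):
        raise ConfigError(f"aggregation must be mean/median/mode, got {aggregation!r}")
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ConfigError("need at least 3 scored subjects")

    outer_preds = np.empty(n)
    selections: list[tuple[int, float, float]] = []
    idx = np.arange(n)
    for i in range(n):
        inner = idx != i
        inner_features = {
            k: np.asarray(F, dtype=float)[inner] for k, F in features_by_k.items()
        }
        combo, _ = _grid_search(
            inner_features, y[inner], grid,
            standardize_scope=standardize_scope, tol=tol, max_iter=max_iter,
        )
        selections.append(combo)
        k, lam, alpha = combo
        F_k = np.asarray(features_by_k[k], dtype=float)
        Ztr, Zte, std = standardize(F_k[inner], F_k[i : i + 1])
        model = fit_enet(Ztr, y[inner], lam, alpha, standardizer=std)
        outer_preds[i] = model.intercept + float((Zte @ model.beta)[0])

    agg_combo = aggregate_hyperparams(selections, aggregation, grid)
    final = _refit_full(features_by_k, y, agg_combo)

    outer_r2, outer_mse, outer_bic = _pooled_metrics(y, outer_preds, final.nonzero_count)
    single_grid = HyperGrid(
        k_values=(agg_combo[0],),
        lambda_values=(agg_combo[1],),
        alpha_values=(agg_combo[2],),
    )
    agg_result = loo_select(
        {agg_combo[0]: features_by_k[agg_combo[0]]}, y, single_grid,
        standardize_scope=standardize_scope, tol=tol, max_iter=max_iter,
    )
    surfaces = {
        "outer": {"r2": outer_r2, "mse": outer_mse, "bic": outer_bic},
        "aggregated": {"r2": agg_result.r2, "mse": agg_result.mse, "bic": agg_result.bic},
    }
    return CVResult(
        scheme="nested_loo", aggregation=aggregation, best_hyperparams=agg_combo,
        predictions=outer_preds, y=y, r2=outer_r2, mse=outer_mse, bic=outer_bic,
        nonzero_count=final.nonzero_count, final_model=final, final_k=agg_combo[0],
        fold_selections=tuple(selections), surfaces=surfaces,
    )


def _snap(value: float, grid_values: Sequence[float], *, log: bool = False) -> float:
    arr = np.asarray(grid_values, dtype=float)
    if log:
        dist = np.abs(np.log10(arr) - np.log10(value))
    else:
        dist = np.abs(arr - value)
    return float(arr[int(np.argmin(dist))])  # first minimum -> smaller value on ties


def _mode(values: Sequence[float]) -> float:
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)  # ties -> smallest


def aggregate_hyperparams(
    selections: Sequence[tuple[int, float, float]],
    rule: str,
    grid: HyperGrid,
) -> tuple[int, float, float]:
    """Central tendency of fold-wise selections, snapped to the grid.

    Mean of lambda is taken on the log10 scale; k and alpha on the natural
    scale.  Mode ties resolve to the smallest value (parsimony).
    """
    if not selections:
        raise ConfigError("empty selection list")
    ks = [s[0] for s in selections]
    lams = [s[1] for s in selections]
    alphas = [s[2] for s in selections]
    if rule == "mean":
        k = float(np.mean(ks))
        lam = float(10 ** np.mean(np.log10(lams)))
        alpha = float(np.mean(alphas))
    elif rule == "median":
        k, lam, alpha = (float(np.median(v)) for v in (ks, lams, alphas))
    elif rule == "mode":
        k, lam, alpha = _mode(ks), _mode(lams), _mode(alphas)
    else:
        raise ConfigError(f"unknown aggregation rule {rule!r}")
    return (
        int(_snap(k, grid.k_values)),
        _snap(lam, grid.lambda_values, log=True),
        _snap(alpha, grid.alpha_values),
    )


def compare_models(
    residuals_by_method: Mapping[str, np.ndarray],
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon signed-rank tests on paired squared residuals.

    Zero differences are dropped; the exact null distribution is used for
    fewer than 25 non-zero differences without rank ties, otherwise the
    normal approximation with continuity correction.  Significance uses a
    Bonferroni-corrected threshold ``alpha_level / m`` over the m pairs.
    """
    names = list(residuals_by_method)
    if len(names) < 2:
        raise ConfigError("need at least 2 methods to compare")
    vecs = {k: np.asarray(v, dtype=float).ravel() for k, v in residuals_by_method.items()}
    n0 = len(next(iter(vecs.values())))
    for k, v in vecs.items():
        if len(v) != n0:
            raise ShapeError(f"residual vector for {k} has length {len(v)} != {n0}")
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        d = vecs[a] - vecs[b]
        nz = d[d != 0]
        if nz.size == 0:
            rows.append((a, b, 0.0, 1.0, "all differences zero"))
            continue
        has_ties = np.unique(np.abs(nz)).size < nz.size
        method = "exact" if (nz.size < 25 and not has_ties) else "approx"
        kwargs = {"correction": True} if method == "approx" else {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(
                vecs[a], vecs[b], zero_method="wilcox",
                alternative="two-sided", method=method, **kwargs,
            )
        rows.append((a, b, float(res.statistic), float(res.pvalue), method))
    df = pd.DataFrame(rows, columns=["method_a", "method_b", "statistic", "p_value", "note"])
    df["m"] = m
    df["threshold"] = alpha_level / m
    df["significant"] = df["p_value"] < df["threshold"]
    return df
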