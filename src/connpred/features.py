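"""Unsupervised feature extraction behind a single linear-model contract.

All four methods expose the same fitted object: a synthesis ``basis``
(p x k) with ``X ~= F @ basis.T + center``, an optional exact analysis map
``forward_map`` (p x k) with ``F = (X - center) @ forward_map`` (PCA, ICA),
and the latent features on the fitted sample.  Reconstruction error is the
elementwise mean squared error between the data and its rank-k
reconstruction, comparable across methods because centering offsets are
added back.

PCA is computed directly by SVD (deterministic, fit once at the largest k
and truncate).  ICA wraps scikit-learn's fixed-point FastICA with
PCA-based whitening, so its rank-k reconstruction coincides with PCA's.
Dictionary learning and nonnegative matrix factorization are implemented
here because their acceptance contract requires a per-iteration objective
trace that is monotone non-increasing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .connectome_data import CohortTable
from .errors import ConfigError, DomainError, NumericalError, RankError, ShapeError

logger = logging.getLogger(__name__)

METHODS = ("pca", "ica", "dl", "nnmf")


@dataclass(frozen=True)
class FeatureModel:
    """A fitted linear feature-extraction model."""

    method: str
    k: int
    basis: np.ndarray                    # p x k, synthesis map
    forward_map: np.ndarray | None       # p x k, analysis map (pca/ica only)
    center: np.ndarray                   # p, zeros if the method does not center
    F_train: np.ndarray                  # n x k latent features on the fit sample
    fit_info: dict[str, Any] = field(default_factory=dict)
    dl_sparsity: float | None = None

    @property
    def n_features(self) -> int:
        return self.basis.shape[0]


def _as_array(X: CohortTable | np.ndarray) -> np.ndarray:
    if isinstance(X, CohortTable):
        return X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError("expected a 2-D subjects-by-edges array")
    return X


def _fix_signs(basis: np.ndarray, *others: np.ndarray) -> tuple[np.ndarray, ...]:
    """Flip columns so the maximum-|loading| entry of each basis column is positive."""
    idx = np.argmax(np.abs(basis), axis=0)
    signs = np.sign(basis[idx, np.arange(basis.shape[1])])
    signs[signs == 0] = 1.0
    return (basis * signs,) + tuple(o * signs for o in others)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(X: CohortTable | np.ndarray, k: int) -> FeatureModel:
    """Principal components of the centered data, by economy SVD.

    Only the first ``n - 1`` components carry variance after centering, so
    ``k`` must satisfy ``1 <= k <= min(n - 1, p)``.  Components are sorted
    by decreasing singular value with a deterministic sign convention.
    """
    X = _as_array(X)
    n, p = X.shape
    if k < 1 or k > p:
        raise RankError(f"k={k} outside [1, p={p}]")
    if k > n - 1:
        raise RankError(f"k={k} exceeds the retainable rank n-1={n - 1}")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    basis = Vt[:k].T
    basis, = _fix_signs(basis)
    F = Xc @ basis
    info = {
        "method": "pca",
        "converged": True,
        "singular_values": s.tolist(),
        "n_samples": n,
    }
    return FeatureModel(
        method="pca", k=k, basis=basis, forward_map=basis,
        center=mu, F_train=F, fit_info=info,
    )


def truncate(model: FeatureModel, k: int) -> FeatureModel:
    """Keep the leading ``k`` components of a PCA model (fit once, truncate)."""
    if model.method != "pca":
        raise ConfigError("truncate is only valid for PCA models")
    if k < 1 or k > model.k:
        raise RankError(f"k={k} outside [1, {model.k}]")
    return replace(
        model,
        k=k,
        basis=model.basis[:, :k],
        forward_map=model.forward_map[:, :k],
        F_train=model.F_train[:, :k],
    )


# ---------------------------------------------------------------------------
# ICA
# ---------------------------------------------------------------------------

def fit_ica(
    X: CohortTable | np.ndarray,
    k: int,
    *,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-4,
) -> FeatureModel:
    """Fixed-point ICA on PCA-whitened data (log-cosh contrast).

    The analysis map is exact: ``F = (X - center) @ forward_map`` with
    unit-variance sources.  Synthesis uses the mixing matrix, so the rank-k
    reconstruction equals the PCA rank-k reconstruction (a rotation within
    the same whitened subspace).  Non-convergence is reported via
    ``fit_info['converged']``, not raised.
    """
    X = _as_array(X)
    n, p = X.shape
    if k < 1 or k > min(n - 1, p):
        raise RankError(f"k={k} outside [1, min(n-1, p)={min(n - 1, p)}]")
    ica = FastICA(
        n_components=k,
        algorithm="parallel",
        whiten="unit-variance",
        fun="logcosh",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        F = ica.fit_transform(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
            logger.warning("FastICA did not converge in %d iterations", max_iter)
    basis = np.asarray(ica.mixing_)
    forward = np.asarray(ica.components_).T
    basis, forward, F = _fix_signs(basis, forward, F)
    info = {
        "method": "ica",
        "seed": seed,
        "iterations": int(ica.n_iter_),
        "converged": converged,
    }
    return FeatureModel(
        method="ica", k=k, basis=basis, forward_map=forward,
        center=np.asarray(ica.mean_), F_train=F, fit_info=info,
    )


# ---------------------------------------------------------------------------
# Dictionary learning
# ---------------------------------------------------------------------------

def _soft(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _lasso_codes(
    X: np.ndarray,
    W: np.ndarray,
    lam: float,
    F0: np.ndarray | None = None,
    max_sweeps: int = 200,
    tol: float = 1e-9,
) -> np.ndarray:
    """Coordinate descent on 0.5*||X - F W^T||^2 + lam*||F||_1, rows jointly.

    The design ``W`` is shared across rows, so each coordinate update is
    vectorized over all rows at once.
    """
    n = X.shape[0]
    k = W.shape[1]
    G = W.T @ W                       # k x k gram
    B = X @ W                         # n x k correlations
    F = np.zeros((n, k)) if F0 is None else F0.copy()
    d = np.diag(G).copy()
    active = d > 0
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(k):
            if not active[j]:
                F[:, j] = 0.0
                continue
            c = B[:, j] - F @ G[:, j] + F[:, j] * d[j]
            new = _soft(c, lam) / d[j]
            delta = np.abs(new - F[:, j]).max(initial=0.0)
            max_delta = max(max_delta, float(delta))
            F[:, j] = new
        if max_delta < tol:
            break
    return F


def _update_dictionary(X: np.ndarray, F: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Block coordinate update of atoms under the unit-ball constraint.

    Each atom's subproblem is an isotropic quadratic, so projecting the
    unconstrained minimizer onto the unit ball is the exact constrained
    minimizer; the joint objective never increases.
    """
    A = F.T @ F                       # k x k
    C = X.T @ F                       # p x k
    W = W.copy()
    d = np.diag(A)
    for j in range(W.shape[1]):
        if d[j] <= 0:
            continue                  # dead atom: leave unchanged
        g = C[:, j] - W @ A[:, j] + W[:, j] * d[j]
        w = g / d[j]
        norm = np.linalg.norm(w)
        if norm > 1.0:
            w /= norm
        W[:, j] = w
    return W


def dl_objective(X: np.ndarray, F: np.ndarray, W: np.ndarray, lam: float) -> float:
    return 0.5 * float(np.sum((X - F @ W.T) ** 2)) + lam * float(np.abs(F).sum())


def fit_dl(
    X: CohortTable | np.ndarray,
    k: int,
    *,
    sparsity: float = 1.0,
    seed: int = 0,
    max_iter: int = 60,
    tol: float = 1e-6,
) -> FeatureModel:
    """Sparse coding by alternating minimization.

    Minimizes ``0.5*||X - F W^T||_F^2 + sparsity*||F||_1`` subject to unit-
    norm-bounded dictionary atoms.  The data are not centered.  The
    objective trace is recorded and checked to be non-increasing.
    """
    X = _as_array(X)
    n, p = X.shape
    if k < 1:
        raise ConfigError("k must be >= 1")
    if sparsity <= 0:
        raise ConfigError("dl sparsity must be > 0")
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((p, k))
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    F = np.zeros((n, k))

    history: list[float] = []
    converged = False
    for it in range(max_iter):
        F = _lasso_codes(X, W, sparsity, F0=F, max_sweeps=30)
        W = _update_dictionary(X, F, W)
        obj = dl_objective(X, F, W, sparsity)
        if not np.isfinite(obj):
            raise NumericalError(f"dictionary learning diverged at iteration {it}")
        history.append(obj)
        if it > 0 and history[-2] - obj <= tol * max(abs(history[-2]), 1.0):
            converged = True
            break
    # final polishing of the codes against the frozen dictionary
    F = _lasso_codes(X, W, sparsity, F0=F)

    info = {
        "method": "dl",
        "seed": seed,
        "iterations": len(history),
        "converged": converged,
        "objective": history[-1],
        "objective_history": history,
    }
    return FeatureModel(
        method="dl", k=k, basis=W, forward_map=None,
        center=np.zeros(p), F_train=F, fit_info=info, dl_sparsity=sparsity,
    )


# ---------------------------------------------------------------------------
# NNMF
# ---------------------------------------------------------------------------

def _nnmf_once(
    V: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    n, p = V.shape
    scale = np.sqrt(max(V.mean(), np.finfo(float).tiny) / k)
    W = scale * rng.random((n, k)) + 1e-4
    H = scale * rng.random((k, p)) + 1e-4
    eps = 1e-12
    history: list[float] = []
    for it in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ (H @ H.T) + eps)
        obj = float(np.sum((V - W @ H) ** 2))
        if not np.isfinite(obj):
            raise NumericalError(f"NNMF objective became non-finite at iteration {it}")
        history.append(obj)
        if it > 0 and history[-2] - obj <= tol * max(history[-2], 1.0):
            break
    return W, H, history


def fit_nnmf(
    X: CohortTable | np.ndarray,
    k: int,
    *,
    seed: int = 0,
    negativity_policy: str = "shift",
    max_iter: int = 200,
    tol: float = 1e-8,
    n_restarts: int = 3,
) -> FeatureModel:
    """Nonnegative matrix factorization by multiplicative updates.

    Negative inputs are handled by ``negativity_policy``: "shift" (default)
    subtracts the global minimum and stores it in ``center`` so the generic
    reconstruction ``F @ basis.T + center`` lives on the original scale;
    "clip" zeroes negatives; "reject" raises.  Multiple seeded restarts are
    run and the best final objective kept.
    """
    X = _as_array(X)
    n, p = X.shape
    if k < 1:
        raise ConfigError("k must be >= 1")
    xmin = float(X.min())
    shift = 0.0
    if xmin < 0:
        if negativity_policy == "reject":
            raise DomainError(
                f"NNMF input has negative entries (min={xmin:.4g}) under policy 'reject'"
            )
        if negativity_policy == "shift":
            shift = xmin
            V = X - shift
        elif negativity_policy == "clip":
            V = np.maximum(X, 0.0)
        else:
            raise ConfigError(f"unknown negativity policy {negativity_policy!r}")
    else:
        V = X

    best: tuple[np.ndarray, np.ndarray, list[float]] | None = None
    for child in np.random.SeedSequence(seed).spawn(max(1, n_restarts)):
        W, H, hist = _nnmf_once(V, k, np.random.default_rng(child), max_iter, tol)
        if best is None or hist[-1] < best[2][-1]:
            best = (W, H, hist)
    W, H, history = best

    info = {
        "method": "nnmf",
        "seed": seed,
        "negativity_policy": negativity_policy,
        "shift": shift,
        "iterations": len(history),
        "converged": len(history) < max_iter,
        "objective": history[-1],
        "objective_history": history,
        "n_restarts": max(1, n_restarts),
    }
    return FeatureModel(
        method="nnmf", k=k, basis=H.T, forward_map=None,
        center=np.full(p, shift), F_train=W, fit_info=info,
    )


# ---------------------------------------------------------------------------
# shared operations
# ---------------------------------------------------------------------------

def transform(model: FeatureModel, X_new: CohortTable | np.ndarray) -> np.ndarray:
    """Map new subjects into the latent feature space.

    PCA/ICA use the exact linear analysis map; DL re-solves the per-row
    L1-penalized code; NNMF solves per-row nonnegative least squares
    against the basis.
    """
    X_new = _as_array(X_new)
    if X_new.shape[1] != model.n_features:
        raise ShapeError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_features}"
        )
    if model.forward_map is not None:
        return (X_new - model.center) @ model.forward_map
    if model.method == "dl":
        return _lasso_codes(X_new, model.basis, model.dl_sparsity)
    if model.method == "nnmf":
        Xs = X_new - model.center
        F = np.empty((Xs.shape[0], model.k))
        for i in range(Xs.shape[0]):
            F[i], _ = nnls(model.basis, Xs[i])
        return F
    raise ConfigError(f"cannot transform with method {model.method!r}")


def reconstruct(model: FeatureModel, X: CohortTable | np.ndarray) -> np.ndarray:
    """Rank-k reconstruction of ``X`` on the original scale."""
    F = transform(model, X)
    return F @ model.basis.T + model.center


def reconstruction_error(model: FeatureModel, X: CohortTable | np.ndarray) -> float:
    """Elementwise mean squared reconstruction error."""
    X = _as_array(X)
    R = X - reconstruct(model, X)
    return float(np.sum(R**2)) / R.size


def default_k_grid() -> tuple[int, ...]:
    """Default grid of candidate feature-set sizes: 10..95 step 5."""
    return tuple(range(10, 96, 5))


def fit_method(
    method: str,
    X: CohortTable | np.ndarray,
    k: int,
    *,
    seed: int = 0,
    **kwargs: Any,
) -> FeatureModel:
    """Dispatch to the per-method fitting routine."""
    if method == "pca":
        return fit_pca(X, k)
    if method == "ica":
        return fit_ica(X, k, seed=seed, **kwargs)
    if method == "dl":
        return fit_dl(X, k, seed=seed, **kwargs)
    if method == "nnmf":
        return fit_nnmf(X, k, seed=seed, **kwargs)
    raise ConfigError(f"unknown method {method!r}; choose from {METHODS}")


def error_curve(
    X: CohortTable | np.ndarray,
    methods: Sequence[str] = METHODS,
    k_grid: Iterable[int] | None = None,
    *,
    seed: int = 0,
    method_kwargs: dict[str, dict[str, Any]] | None = None,
) -> pd.DataFrame:
    """Reconstruction MSE per (method, k).

    PCA is fit once at the largest admissible k and truncated; the other
    methods are refit at each k.  Grid values above ``n - 1`` are dropped
    with a warning.
    """
    Xa = _as_array(X)
    n = Xa.shape[0]
    ks = sorted(set(int(k) for k in (k_grid if k_grid is not None else default_k_grid())))
    admissible = [k for k in ks if 1 <= k <= min(n - 1, Xa.shape[1])]
    if len(admissible) < len(ks):
        logger.warning(
            "dropped %d k values above the retainable rank n-1=%d",
            len(ks) - len(admissible), n - 1,
        )
    if not admissible:
        raise ConfigError("no admissible k values in the grid")
    kwargs_by_method = method_kwargs or {}
    rows = []
    for mi, method in enumerate(methods):
        if method == "pca":
            full = fit_pca(Xa, max(admissible))
            for k in admissible:
                rows.append((method, k, reconstruction_error(truncate(full, k), Xa)))
        else:
            for ki, k in enumerate(admissible):
                model = fit_method(
                    method, Xa, k,
                    seed=seed + 1000 * mi + ki,
                    **kwargs_by_method.get(method, {}),
                )
                rows.append((method, k, reconstruction_error(model, Xa)))
    return pd.DataFrame(rows, columns=["method", "k", "mse"])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_feature_model(model: FeatureModel, outdir) -> None:
    """Write basis/forward_map/center/F_train as delimited text + JSON fit_info."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "basis.csv", model.basis, delimiter=",")
    if model.forward_map is not None:
        np.savetxt(outdir / "forward_map.csv", model.forward_map, delimiter=",")
    np.savetxt(outdir / "center.csv", model.center, delimiter=",")
    np.savetxt(outdir / "F_train.csv", model.F_train, delimiter=",")
    meta = {
        "method": model.method,
        "k": model.k,
        "dl_sparsity": model.dl_sparsity,
        "fit_info": model.fit_info,
    }
    (outdir / "fit_info.json").write_text(json.dumps(meta, indent=2))


def load_feature_model(indir) -> FeatureModel:
    import json
    from pathlib import Path

    indir = Path(indir)
    meta = json.loads((indir / "fit_info.json").read_text())
    basis = np.loadtxt(indir / "basis.csv", delimiter=",", ndmin=2)
    fm_path = indir / "forward_map.csv"
    forward = np.loadtxt(fm_path, delimiter=",", ndmin=2) if fm_path.exists() else None
    return FeatureModel(
        method=meta["method"],
        k=int(meta["k"]),
        basis=basis,
        forward_map=forward,
        center=np.loadtxt(indir / "center.csv", delimiter=","),
        F_train=np.loadtxt(indir / "F_train.csv", delimiter=",", ndmin=2),
        fit_info=meta["fit_info"],
        dl_sparsity=meta["dl_sparsity"],
    )
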