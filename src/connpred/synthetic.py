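"""Synthetic cohort generator with known low-rank ground truth.

The generative model is ``X = F W^T + noise`` with network-block-structured
loadings ``W`` and latent subject scores ``F``; the behavioral score is a
linear function of a small subset of the latent components plus noise.  All
quantities needed for parameter-recovery tests (loadings, latent scores,
regression coefficients, the implied edge map, and the realized fraction of
score variance that is explainable) are returned alongside the cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .connectome_data import (
    BehavioralScores,
    CohortTable,
    ParcelAtlas,
    edge_index,
    n_edges,
)
from .errors import ConfigError


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort generator.

    Defaults give a desk-scale problem (p = 2016 edges) on which the full
    pipeline, grid search included, runs in minutes.
    """

    P: int = 64
    n: int = 100
    k_true: int = 10
    M: int = 8
    noise_sd: float = 0.05
    score_noise_sd: float = 0.8165
    n_predictive: int = 3
    nonnegative: bool = False
    seed: int = 0
    intercept: float = 0.0
    signal_strength: float = 1.0
    background_sd: float = 0.05
    unscored_fraction: float = 0.0
    tanh_squash: bool = False

    @property
    def p(self) -> int:
        return n_edges(self.P)

    def validate(self) -> None:
        if self.P < 3:
            raise ConfigError("P must be >= 3")
        if self.k_true >= min(self.n, self.p):
            raise ConfigError(
                f"k_true={self.k_true} must be < min(n, p)={min(self.n, self.p)}"
            )
        if not (1 <= self.n_predictive <= self.k_true):
            raise ConfigError("need 1 <= n_predictive <= k_true")
        if self.noise_sd < 0 or self.score_noise_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        if not (0 <= self.unscored_fraction < 1):
            raise ConfigError("unscored_fraction must be in [0, 1)")
        if self.M < 1 or self.M > self.P:
            raise ConfigError("need 1 <= M <= P")


@dataclass(frozen=True)
class GroundTruth:
    """Generative quantities for recovery testing."""

    W_true: np.ndarray          # p x k_true, unit-norm columns
    F_true: np.ndarray          # n x k_true
    b_true: np.ndarray          # k_true, zeros outside the predictive set
    intercept_true: float
    m_true: np.ndarray          # p, = W_true @ b_true
    realized_R2: float


def noise_sd_for_snr(config: SyntheticConfig, snr: float) -> float:
    """Edge noise level giving a target average edge-level SNR.

    With unit-variance latent scores and unit-norm loading columns, the
    average per-edge signal variance is ``k_true / p``; SNR is defined as
    that average divided by ``noise_sd**2``.
    """
    if snr <= 0:
        raise ConfigError("snr must be positive")
    return float(np.sqrt(config.k_true / (snr * config.p)))


def score_noise_sd_for_r2(config: SyntheticConfig, r2: float) -> float:
    """Score noise level whose expected realized R^2 is ``r2``.

    The signal variance of ``F b`` is ``|b|^2 = signal_strength**2`` since
    latent columns are independent unit-variance.
    """
    if not (0 < r2 <= 1):
        raise ConfigError("r2 must be in (0, 1]")
    return float(config.signal_strength * np.sqrt(1.0 / r2 - 1.0))


def _network_of_edges(atlas: ParcelAtlas) -> np.ndarray:
    """(p, 2) array of network indices for both endpoints of each edge."""
    nets = atlas.networks
    net_idx = np.array([nets.index(lab) for lab in atlas.network_labels])
    ij = edge_index(atlas.n_parcels)
    return net_idx[ij]


def make_loadings(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the ``p x k_true`` loading matrix with network-block structure.

    Each column concentrates its mass on the edges of one to three randomly
    chosen network-pair blocks (within- or between-network), on top of a
    small dense background; columns are normalized to unit Euclidean norm.
    """
    config.validate()
    atlas = ParcelAtlas.generic(config.P, config.M)
    enet = _network_of_edges(atlas)
    p, k, M = config.p, config.k_true, config.M

    W = rng.normal(0.0, config.background_sd, size=(p, k))
    for c in range(k):
        n_blocks = int(rng.integers(1, 4))
        for _ in range(n_blocks):
            a, b = sorted(rng.integers(0, M, size=2))
            in_block = (np.minimum(enet[:, 0], enet[:, 1]) == a) & (
                np.maximum(enet[:, 0], enet[:, 1]) == b
            )
            W[in_block, c] += rng.normal(0.0, 1.0, size=int(in_block.sum()))
    if config.nonnegative:
        W = np.abs(W)
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    return W


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[CohortTable, BehavioralScores, GroundTruth]:
    """Generate a cohort, behavioral scores, and the ground truth bundle.

    Fully reproducible from ``config.seed``.  In nonnegative mode the latent
    scores and the additive noise are half-normal so the data matrix is
    entrywise nonnegative.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_w, rng_f, rng_e, rng_y, rng_miss = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    atlas = ParcelAtlas.generic(config.P, config.M)
    W = make_loadings(config, rng_w)

    F = rng_f.standard_normal((config.n, config.k_true))
    E = rng_e.standard_normal((config.n, config.p))
    if config.nonnegative:
        F = np.abs(F)
        E = np.abs(E)

    X = F @ W.T + config.noise_sd * E
    if config.tanh_squash:
        X = np.tanh(X)

    b = np.zeros(config.k_true)
    b[: config.n_predictive] = config.signal_strength / np.sqrt(config.n_predictive)
    y_signal = config.intercept + F @ b
    eps = rng_y.standard_normal(config.n)
    y = y_signal + config.score_noise_sd * eps

    # realized R^2: fraction of observed score variance explained by the
    # noiseless signal, 1 - SS(y - y_signal)/SS(y - mean(y))
    ss_res = float(np.sum((y - y_signal) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    realized_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    subject_ids = tuple(f"S{i:04d}" for i in range(config.n))
    scores = dict(zip(subject_ids, y.tolist()))
    if config.unscored_fraction > 0:
        n_drop = int(round(config.unscored_fraction * config.n))
        drop = rng_miss.choice(config.n, size=n_drop, replace=False)
        for i in drop:
            scores[subject_ids[i]] = float("nan")

    cohort = CohortTable(X=X, subject_ids=subject_ids, atlas=atlas)
    behavioral = BehavioralScores(scores=scores, domain="synthetic")
    truth = GroundTruth(
        W_true=W,
        F_true=F,
        b_true=b,
        intercept_true=config.intercept,
        m_true=W @ b,
        realized_R2=realized_r2,
    )
    return cohort, behavioral, truth


def write_ground_truth(truth: GroundTruth, config: SyntheticConfig, outdir: str | Path) -> None:
    """Write W_true/b_true/m_true as delimited text plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "W_true.csv", truth.W_true, delimiter=",")
    np.savetxt(outdir / "b_true.csv", truth.b_true, delimiter=",")
    np.savetxt(outdir / "m_true.csv", truth.m_true, delimiter=",")
    manifest = dataclasses.asdict(config)
    manifest["realized_R2"] = truth.realized_R2
    manifest["intercept_true"] = truth.intercept_true
    (outdir / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
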