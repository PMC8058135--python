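"""Back-projection of regression coefficients into edge space.

Standardized coefficients are rescaled to the raw feature scale, then
pushed through the extraction model's linear weights: the analysis map
when one exists (PCA, ICA — making edge-space predictions exactly
reproduce feature-space predictions) or the synthesis basis/dictionary
otherwise (DL, NNMF).  The resulting edge-weight vector is restored to a
symmetric parcel-by-parcel matrix for ranking and summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .connectome_data import ParcelAtlas, edge_index, n_edges, restore_symmetric
from .errors import ConfigError, DomainError, ModelError, ShapeError
from .features import FeatureModel
from .regression import RegressionModel


@dataclass(frozen=True)
class PredictiveMap:
    """Edge-space weight vector with provenance."""

    edge_weights: np.ndarray
    atlas: ParcelAtlas
    provenance: dict[str, Any] = field(default_factory=dict)
    intercept_adjusted: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.edge_weights, dtype=float).ravel()
        if w.size != n_edges(self.atlas.n_parcels):
            raise ShapeError(
                f"edge weights of length {w.size} do not match atlas "
                f"P={self.atlas.n_parcels}"
            )
        object.__setattr__(self, "edge_weights", w)

    @property
    def matrix_form(self) -> np.ndarray:
        return restore_symmetric(self.edge_weights, self.atlas.n_parcels)

    @property
    def n_parcels(self) -> int:
        return self.atlas.n_parcels


def back_project(
    fm: FeatureModel, rm: RegressionModel, atlas: ParcelAtlas
) -> PredictiveMap:
    """Map regression coefficients back to edge space.

    Coefficients are first un-standardized (``beta_raw_j = beta_j / sd_j``)
    and then linearly transformed through the feature weights.  The
    adjusted intercept makes ``X @ edge_weights + intercept_adjusted``
    reproduce feature-space predictions exactly for methods with an
    analysis map.
    """
    if fm.k != rm.beta.size:
        raise ShapeError(f"model has k={fm.k} features but {rm.beta.size} coefficients")
    T = fm.forward_map if fm.forward_map is not None else fm.basis
    if T is None:
        raise ModelError("feature model exposes neither forward_map nor basis")
    source = "forward_map" if fm.forward_map is not None else "basis"
    beta_raw = rm.beta / rm.standardizer.sds
    m = T @ beta_raw
    intercept_adj = (
        rm.intercept
        - float(rm.standardizer.means @ beta_raw)
        - float(fm.center @ m)
    )
    provenance = {
        "method": fm.method,
        "k": fm.k,
        "lambda": rm.lam,
        "alpha": rm.alpha,
        "transform_source": source,
    }
    return PredictiveMap(
        edge_weights=m, atlas=atlas, provenance=provenance,
        intercept_adjusted=intercept_adj,
    )


def top_edges(pmap: PredictiveMap, N: int = 200) -> pd.DataFrame:
    """The N largest-|weight| edges, ranked; ties in |weight| break by edge index."""
    p = pmap.edge_weights.size
    if N > p:
        raise ConfigError(f"N={N} exceeds the number of edges p={p}")
    w = pmap.edge_weights
    order = np.lexsort((np.arange(p), -np.abs(w)))[:N]
    ij = edge_index(pmap.n_parcels)[order]
    atlas = pmap.atlas
    return pd.DataFrame(
        {
            "rank": np.arange(1, N + 1),
            "parcel_i": ij[:, 0],
            "parcel_j": ij[:, 1],
            "parcel_i_name": [atlas.parcel_names[i] for i in ij[:, 0]],
            "parcel_j_name": [atlas.parcel_names[j] for j in ij[:, 1]],
            "network_i": [atlas.network_labels[i] for i in ij[:, 0]],
            "network_j": [atlas.network_labels[j] for j in ij[:, 1]],
            "weight": w[order],
            "sign": np.sign(w[order]).astype(int),
        }
    )


def map_correlation(a: PredictiveMap, b: PredictiveMap) -> float:
    """Pearson correlation between two edge-weight vectors."""
    if a.edge_weights.size != b.edge_weights.size:
        raise ShapeError("maps have different numbers of edges")
    for name, v in (("first", a.edge_weights), ("second", b.edge_weights)):
        if np.std(v) == 0:
            raise DomainError(f"{name} map has zero variance")
    return float(np.corrcoef(a.edge_weights, b.edge_weights)[0, 1])


def node_contribution(
    table: pd.DataFrame, n_parcels: int | None = None, *, normalize: bool = True
) -> np.ndarray:
    """Per-parcel sum of |weight| over the selected incident edges.

    Normalized so the largest contribution is 1 unless ``normalize=False``.
    """
    if table.empty:
        raise ConfigError("empty edge table")
    P = n_parcels if n_parcels is not None else int(table[["parcel_i", "parcel_j"]].to_numpy().max()) + 1
    contrib = np.zeros(P)
    absw = np.abs(table["weight"].to_numpy())
    np.add.at(contrib, table["parcel_i"].to_numpy(), absw)
    np.add.at(contrib, table["parcel_j"].to_numpy(), absw)
    peak = contrib.max()
    if normalize and peak > 0:
        contrib = contrib / peak
    return contrib


def network_block_summary(pmap: PredictiveMap) -> pd.DataFrame:
    """Mean |weight| per network-pair block (within- and between-network)."""
    atlas = pmap.atlas
    nets = atlas.networks
    net_idx = np.array([nets.index(lab) for lab in atlas.network_labels])
    ij = edge_index(atlas.n_parcels)
    a = np.minimum(net_idx[ij[:, 0]], net_idx[ij[:, 1]])
    b = np.maximum(net_idx[ij[:, 0]], net_idx[ij[:, 1]])
    M = len(nets)
    sums = np.zeros((M, M))
    counts = np.zeros((M, M))
    np.add.at(sums, (a, b), np.abs(pmap.edge_weights))
    np.add.at(counts, (a, b), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    means = np.triu(means) + np.triu(means, 1).T  # symmetric
    return pd.DataFrame(means, index=list(nets), columns=list(nets))


def export_map(pmap: PredictiveMap, outdir: str | Path, prefix: str = "map", top_n: int = 200) -> None:
    """Write the square matrix, ranked edge table (1-based ids), block table
    and node-contribution file for external viewers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / f"{prefix}_matrix.csv", pmap.matrix_form, delimiter=",")
    table = top_edges(pmap, min(top_n, pmap.edge_weights.size))
    exported = table.copy()
    exported["parcel_i"] = exported["parcel_i"] + 1
    exported["parcel_j"] = exported["parcel_j"] + 1
    exported.to_csv(outdir / f"{prefix}_top_edges.csv", index=False)
    network_block_summary(pmap).to_csv(outdir / f"{prefix}_network_blocks.csv")
    contrib = node_contribution(table, pmap.n_parcels)
    nodes = pd.DataFrame(
        {
            "parcel_id": np.arange(1, pmap.n_parcels + 1),
            "parcel_name": pmap.atlas.parcel_names,
            "contribution": contrib,
        }
    )
    if pmap.atlas.coordinates is not None:
        nodes[["x", "y", "z"]] = pmap.atlas.coordinates
    nodes.to_csv(outdir / f"{prefix}_nodes.csv", index=False)
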