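"""Data model and I/O for parcels, connectivity matrices, edge vectors and cohorts.

Conventions
-----------
* Parcels are indexed ``0..P-1`` internally; exported tables are 1-based.
* Edge vectorization uses the row-major upper triangle excluding the
  diagonal: ``(0,1), (0,2), ..., (0,P-1), (1,2), ...``.  A symmetric
  ``P x P`` matrix therefore maps to ``P*(P-1)/2`` edges.
* The diagonal (self-connectivity) is discarded everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AsymmetryError,
    DataError,
    FormatError,
    InsufficientDataError,
    ShapeError,
)

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8


def n_edges(P: int) -> int:
    """Number of unique off-diagonal edges of a ``P x P`` symmetric matrix."""
    return P * (P - 1) // 2


def edge_index(P: int) -> np.ndarray:
    """Canonical (i, j) pairs, i < j, in row-major upper-triangle order.

    Returns an ``(n_edges(P), 2)`` integer array.
    """
    iu, ju = np.triu_indices(P, k=1)
    return np.column_stack([iu, ju])


@dataclass(frozen=True)
class ParcelAtlas:
    """Parcel labels and network membership.

    Parameters
    ----------
    parcel_names : sequence of str, one per parcel.
    network_labels : sequence of str, one per parcel.
    coordinates : optional (P, 3) float array, export only.
    """

    parcel_names: tuple[str, ...]
    network_labels: tuple[str, ...]
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.parcel_names) != len(self.network_labels):
            raise ShapeError(
                f"{len(self.parcel_names)} parcel names but "
                f"{len(self.network_labels)} network labels"
            )
        if len(self.parcel_names) < 2:
            raise DataError("atlas needs at least 2 parcels")
        if self.coordinates is not None:
            coords = np.asarray(self.coordinates, dtype=float)
            if coords.shape != (len(self.parcel_names), 3):
                raise ShapeError("coordinates must be (P, 3)")
            object.__setattr__(self, "coordinates", coords)

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_names)

    @property
    def networks(self) -> tuple[str, ...]:
        """Distinct network labels in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.network_labels:
            seen.setdefault(lab)
        return tuple(seen)

    @property
    def n_networks(self) -> int:
        return len(self.networks)

    @classmethod
    def generic(cls, P: int, M: int = 1) -> "ParcelAtlas":
        """Atlas of ``P`` parcels split into ``M`` contiguous networks."""
        if M < 1 or M > P:
            raise DataError(f"need 1 <= M <= P, got M={M}, P={P}")
        bounds = np.linspace(0, P, M + 1).astype(int)
        labels = []
        for m in range(M):
            labels.extend([f"net{m + 1:02d}"] * (bounds[m + 1] - bounds[m]))
        names = tuple(f"parcel{i + 1:04d}" for i in range(P))
        return cls(parcel_names=names, network_labels=tuple(labels))

    @classmethod
    def from_file(cls, path: str | Path) -> "ParcelAtlas":
        df = _read_table(path)
        required = {"parcel_id", "parcel_name", "network_label"}
        if not required.issubset(df.columns):
            raise FormatError(
                f"atlas file {path} must have columns {sorted(required)}"
            )
        df = df.sort_values("parcel_id").reset_index(drop=True)
        ids = df["parcel_id"].to_numpy()
        start = int(ids[0])
        if start not in (0, 1) or not np.array_equal(ids, np.arange(start, start + len(ids))):
            raise DataError("parcel_ids must be contiguous starting at 0 or 1")
        coords = None
        if {"x", "y", "z"}.issubset(df.columns):
            coords = df[["x", "y", "z"]].to_numpy(dtype=float)
        return cls(
            parcel_names=tuple(df["parcel_name"].astype(str)),
            network_labels=tuple(df["network_label"].astype(str)),
            coordinates=coords,
        )

    def to_file(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "parcel_id": np.arange(1, self.n_parcels + 1),
                "parcel_name": self.parcel_names,
                "network_label": self.network_labels,
            }
        )
        if self.coordinates is not None:
            df[["x", "y", "z"]] = self.coordinates
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class ConnectomeMatrix:
    """One subject's symmetric ``P x P`` connectivity matrix."""

    values: np.ndarray
    atlas: ParcelAtlas

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError(f"expected square matrix, got shape {v.shape}")
        if v.shape[0] != self.atlas.n_parcels:
            raise ShapeError(
                f"matrix is {v.shape[0]}x{v.shape[0]} but atlas has "
                f"{self.atlas.n_parcels} parcels"
            )
        object.__setattr__(self, "values", v)

    @property
    def n_parcels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EdgeVector:
    """Vectorized upper triangle of a connectivity matrix."""

    values: np.ndarray
    n_parcels: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size != n_edges(self.n_parcels):
            raise ShapeError(
                f"edge vector of length {v.size} does not match P="
                f"{self.n_parcels} (expected {n_edges(self.n_parcels)})"
            )
        object.__setattr__(self, "values", v)

    @property
    def edge_index(self) -> np.ndarray:
        return edge_index(self.n_parcels)


@dataclass(frozen=True)
class CohortTable:
    """Subjects-by-edges data matrix aligned to subject ids."""

    X: np.ndarray
    subject_ids: tuple[str, ...]
    atlas: ParcelAtlas

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ShapeError("cohort X must be 2-D")
        if X.shape[0] != len(self.subject_ids):
            raise ShapeError(
                f"{X.shape[0]} rows but {len(self.subject_ids)} subject ids"
            )
        p_expect = n_edges(self.atlas.n_parcels)
        if X.shape[1] != p_expect:
            raise ShapeError(
                f"cohort has p={X.shape[1]} edges but atlas with "
                f"P={self.atlas.n_parcels} implies p={p_expect}"
            )
        if not np.isfinite(X).all():
            raise DataError("cohort matrix contains non-finite values")
        const = np.ptp(X, axis=0) == 0
        if X.shape[0] > 1 and const.any():
            logger.warning("%d all-constant edge columns in cohort", const.sum())
        object.__setattr__(self, "X", X)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class BehavioralScores:
    """Per-subject behavioral score for one cognitive domain.

    Missing scores are allowed (``NaN`` or absent ids).  Sign convention:
    deficits are negative.
    """

    scores: Mapping[str, float]
    domain: str = "score"

    def available(self) -> dict[str, float]:
        return {
            sid: float(v)
            for sid, v in self.scores.items()
            if v is not None and np.isfinite(v)
        }


def vectorize_connectome(m: ConnectomeMatrix, *, force: bool = False) -> EdgeVector:
    """Extract the upper-triangle edges of a symmetric connectivity matrix.

    Parameters
    ----------
    m : ConnectomeMatrix
    force : bool
        If True, symmetrize ``(m + m.T) / 2`` instead of raising on
        asymmetry beyond tolerance.

    Returns
    -------
    EdgeVector of length ``P*(P-1)/2`` in canonical row-major order.
    """
    v = m.values
    if not np.isfinite(v).all():
        raise DataError("connectivity matrix contains non-finite entries")
    asym = np.abs(v - v.T).max()
    if asym > SYMMETRY_TOL:
        if not force:
            raise AsymmetryError(
                f"matrix asymmetric beyond tolerance ({asym:.3g} > {SYMMETRY_TOL:g}); "
                "pass force=True to symmetrize"
            )
        v = (v + v.T) / 2.0
    P = v.shape[0]
    iu, ju = np.triu_indices(P, k=1)
    return EdgeVector(values=v[iu, ju], n_parcels=P)


def restore_symmetric(v: EdgeVector | np.ndarray, P: int | None = None) -> np.ndarray:
    """Rebuild the symmetric ``P x P`` matrix from an edge vector.

    The diagonal is set to zero.  Exact inverse of
    :func:`vectorize_connectome` on the off-diagonal entries.
    """
    if isinstance(v, EdgeVector):
        P = v.n_parcels
        vals = v.values
    else:
        if P is None:
            raise ShapeError("P is required when passing a raw array")
        vals = np.asarray(v, dtype=float).ravel()
        if vals.size != n_edges(P):
            raise ShapeError(
                f"vector of length {vals.size} does not match P={P} "
                f"(expected {n_edges(P)})"
            )
    out = np.zeros((P, P), dtype=float)
    iu, ju = np.triu_indices(P, k=1)
    out[iu, ju] = vals
    out[ju, iu] = vals
    return out


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with a header row."""
    path = Path(path)
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise FormatError(f"could not parse {path}: {exc}") from exc


def _read_matrix(path: str | Path) -> np.ndarray:
    """Read a square numeric matrix from delimited text (no header)."""
    path = Path(path)
    for delim in (None, ","):
        try:
            arr = np.loadtxt(path, delimiter=delim, ndmin=2)
        except ValueError:
            continue
        if arr.shape[0] == arr.shape[1]:
            return arr
    raise FormatError(f"{path} is not a square delimited numeric matrix")


def load_cohort(
    matrix_files: Sequence[str | Path] | None = None,
    cohort_file: str | Path | None = None,
    atlas_file: str | Path | None = None,
    atlas: ParcelAtlas | None = None,
    subject_ids: Sequence[str] | None = None,
) -> CohortTable:
    """Assemble a :class:`CohortTable` from files.

    Two accepted forms: a list of per-subject square delimited matrices
    (``matrix_files``), or one subjects-by-edges delimited table
    (``cohort_file``).  Subject order follows input order.
    """
    if atlas is None:
        if atlas_file is None:
            raise FormatError("either atlas or atlas_file is required")
        atlas = ParcelAtlas.from_file(atlas_file)

    if (matrix_files is None) == (cohort_file is None):
        raise FormatError("pass exactly one of matrix_files or cohort_file")

    if matrix_files is not None:
        rows = []
        for f in matrix_files:
            m = _read_matrix(f)
            if m.shape[0] != atlas.n_parcels:
                raise ShapeError(
                    f"{f}: matrix is {m.shape[0]}x{m.shape[1]} but atlas has "
                    f"P={atlas.n_parcels} parcels"
                )
            rows.append(vectorize_connectome(ConnectomeMatrix(m, atlas)).values)
        X = np.vstack(rows)
        if subject_ids is None:
            subject_ids = tuple(Path(f).stem for f in matrix_files)
    else:
        df = _read_table(cohort_file)
        if df.columns[0].lower() in ("subject_id", "subject", "id"):
            ids = tuple(df.iloc[:, 0].astype(str))
            X = df.iloc[:, 1:].to_numpy(dtype=float)
        else:
            ids = tuple(f"S{i:04d}" for i in range(len(df)))
            X = df.to_numpy(dtype=float)
        if subject_ids is None:
            subject_ids = ids
        if X.shape[1] != n_edges(atlas.n_parcels):
            raise ShapeError(
                f"cohort table has p={X.shape[1]} but atlas P={atlas.n_parcels} "
                f"implies p={n_edges(atlas.n_parcels)}"
            )

    table = CohortTable(X=X, subject_ids=tuple(map(str, subject_ids)), atlas=atlas)
    logger.info(
        "loaded cohort: n=%d subjects, p=%d edges, P=%d parcels",
        table.n_subjects, table.n_edges, atlas.n_parcels,
    )
    return table


def load_scores(path: str | Path, domain: str | None = None) -> BehavioralScores:
    """Read scores from a table with columns subject_id, [domain,] score."""
    df = _read_table(path)
    if "subject_id" not in df.columns or "score" not in df.columns:
        raise FormatError(f"{path} must have subject_id and score columns")
    if "domain" in df.columns and domain is not None:
        df = df[df["domain"] == domain]
    name = domain or (str(df["domain"].iloc[0]) if "domain" in df.columns and len(df) else "score")
    scores = {
        str(r.subject_id): (float(r.score) if pd.notna(r.score) else float("nan"))
        for r in df.itertuples()
    }
    return BehavioralScores(scores=scores, domain=name)


def align_scores(
    cohort: CohortTable, scores: BehavioralScores
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Subset the cohort to subjects with an available score.

    Returns ``(X_sub, y, kept_subject_ids)`` with rows in cohort order.
    """
    available = scores.available()
    keep = [i for i, sid in enumerate(cohort.subject_ids) if sid in available]
    if len(keep) < 3:
        raise InsufficientDataError(
            f"only {len(keep)} subjects have a score; need at least 3"
        )
    kept_ids = tuple(cohort.subject_ids[i] for i in keep)
    y = np.array([available[sid] for sid in kept_ids], dtype=float)
    return cohort.X[keep], y, kept_ids


def write_scores(scores: BehavioralScores, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "subject_id": list(scores.scores),
            "domain": scores.domain,
            "score": [scores.scores[s] for s in scores.scores],
        }
    )
    df.to_csv(path, index=False)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the subjects-by-edges table with a subject_id column."""
    df = pd.DataFrame(cohort.X)
    df.insert(0, "subject_id", list(cohort.subject_ids))
    df.to_csv(path, index=False)
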