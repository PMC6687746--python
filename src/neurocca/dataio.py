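"""Containers and I/O for two-view subject data.

The analysis operates on two subjects x variables matrices -- a brain view
(vectorized functional-connectivity edges) and a behaviour view
(questionnaire items, IQ, demographics) -- plus per-subject confounds
(head motion, scanner site) and region metadata.  This module defines the
containers, the canonical edge-vectorization of symmetric connectivity
matrices, subject alignment across views, and delimited-text round trips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Maximum absolute asymmetry tolerated in a connectivity matrix before it is
#: rejected (never silently symmetrized).
SYMMETRY_TOL = 1e-8


@dataclass
class DataMatrix:
    """A subjects x variables real matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_subjects, n_variables)
        Matrix entries.  NaN marks a missing entry and is only legal when
        ``allow_missing`` is true (behaviour view before imputation).
    subject_ids, variable_ids : sequences of unique str
        Row and column identifiers.
    allow_missing : bool
        Whether NaN entries are permitted.
    """

    values: np.ndarray
    subject_ids: list[str]
    variable_ids: list[str]
    allow_missing: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.variable_ids = [str(v) for v in self.variable_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x variables)")
        n, m = self.values.shape
        if n != len(self.subject_ids):
            raise ValueError(
                f"{n} rows but {len(self.subject_ids)} subject_ids"
            )
        if m != len(self.variable_ids):
            raise ValueError(
                f"{m} columns but {len(self.variable_ids)} variable_ids"
            )
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject_ids")
        if len(set(self.variable_ids)) != m:
            raise ValueError("duplicate variable_ids")
        if not self.allow_missing and not np.isfinite(self.values).all():
            raise ValueError("non-finite values in a matrix that forbids missing data")
        if self.allow_missing and np.isinf(self.values).any():
            raise ValueError("infinite values are never allowed")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.variable_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, allow_missing: bool = False) -> "DataMatrix":
        return cls(
            frame.to_numpy(dtype=float),
            list(frame.index.astype(str)),
            list(frame.columns.astype(str)),
            allow_missing=allow_missing,
        )

    def subset_subjects(self, ids: Sequence[str]) -> "DataMatrix":
        """Restrict to ``ids`` in the given order."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in ids]
        return DataMatrix(
            self.values[idx], list(ids), list(self.variable_ids), self.allow_missing
        )

    def subset_variables(self, ids: Sequence[str]) -> "DataMatrix":
        pos = {v: i for i, v in enumerate(self.variable_ids)}
        idx = [pos[v] for v in ids]
        return DataMatrix(
            self.values[:, idx], list(self.subject_ids), list(ids), self.allow_missing
        )


@dataclass
class ConnectivityProfile:
    """An r x r symmetric Pearson-correlation matrix over brain regions."""

    matrix: np.ndarray
    region_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.region_ids = [str(r) for r in self.region_ids]
        r = len(self.region_ids)
        if self.matrix.shape != (r, r):
            raise ValueError(f"matrix shape {self.matrix.shape} != ({r}, {r})")
        if len(set(self.region_ids)) != r:
            raise ValueError("duplicate region_ids")
        asym = np.abs(self.matrix - self.matrix.T).max() if r else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"matrix asymmetric beyond tolerance (max |A-A'| = {asym:g})")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-6):
            raise ValueError("diagonal entries must equal 1")
        off = self.matrix[~np.eye(r, dtype=bool)]
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("off-diagonal correlations outside [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


class EdgeIndex:
    """Bijection between edge-vector positions and unordered region pairs.

    The ordering is the row-major upper triangle with i < j:
    (1,2), (1,3), ..., (1,r), (2,3), ..., (r-1,r).  For r regions the
    index has r(r-1)/2 entries -- e.g. 348 regions give 60378 edges.
    """

    def __init__(self, region_ids: Sequence[str]):
        self.region_ids = [str(r) for r in region_ids]
        r = len(self.region_ids)
        if len(set(self.region_ids)) != r:
            raise ValueError("duplicate region_ids")
        self._rows, self._cols = np.triu_indices(r, k=1)

    def __len__(self) -> int:
        return len(self._rows)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [
            (self.region_ids[i], self.region_ids[j])
            for i, j in zip(self._rows, self._cols)
        ]

    def edge_ids(self) -> list[str]:
        """Stable string ids of the form 'regionA--regionB'."""
        return [f"{a}--{b}" for a, b in self.pairs]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EdgeIndex) and self.region_ids == other.region_ids


@dataclass
class ConfoundTable:
    """Per-subject confounds: mean/max framewise displacement (mm) and site."""

    subject_ids: list[str]
    mean_fd: np.ndarray
    max_fd: np.ndarray
    site: list[str]
    site_levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.mean_fd = np.asarray(self.mean_fd, dtype=float)
        self.max_fd = np.asarray(self.max_fd, dtype=float)
        self.site = [str(s) for s in self.site]
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject_ids")
        if not (len(self.mean_fd) == len(self.max_fd) == len(self.site) == n):
            raise ValueError("confound columns must have one row per subject")
        if np.isnan(self.mean_fd).any() or np.isnan(self.max_fd).any():
            raise ValueError("missing framewise-displacement values")
        if (self.mean_fd < 0).any() or (self.max_fd < 0).any():
            raise ValueError("framewise displacement must be non-negative")
        if not self.site_levels:
            self.site_levels = sorted(set(self.site))
        unknown = set(self.site) - set(self.site_levels)
        if unknown:
            raise ValueError(f"site labels outside declared levels: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset_subjects(self, ids: Sequence[str]) -> "ConfoundTable":
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in ids]
        return ConfoundTable(
            list(ids),
            self.mean_fd[idx],
            self.max_fd[idx],
            [self.site[i] for i in idx],
            list(self.site_levels),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mean_fd": self.mean_fd, "max_fd": self.max_fd, "site": self.site},
            index=self.subject_ids,
        )


@dataclass
class DatasetBundle:
    """Brain view, behaviour view and confounds with identical subject order."""

    brain: DataMatrix
    behaviour: DataMatrix
    confounds: ConfoundTable

    def __post_init__(self) -> None:
        ids = self.brain.subject_ids
        if self.behaviour.subject_ids != ids or self.confounds.subject_ids != ids:
            raise ValueError("subject_ids differ across bundle members")

    @property
    def subject_ids(self) -> list[str]:
        return self.brain.subject_ids

    @property
    def n_subjects(self) -> int:
        return self.brain.n_subjects

    def subset_subjects(self, ids: Sequence[str]) -> "DatasetBundle":
        return DatasetBundle(
            self.brain.subset_subjects(ids),
            self.behaviour.subset_subjects(ids),
            self.confounds.subset_subjects(ids),
        )


# ---------------------------------------------------------------------------
# Edge vectorization


def vectorize_connectivity(
    profile: ConnectivityProfile,
) -> tuple[np.ndarray, EdgeIndex]:
    """Flatten a symmetric connectivity matrix into its upper-triangle edges.

    Returns the length-r(r-1)/2 edge vector and the :class:`EdgeIndex`
    fixing the pair ordering.  A 348-region profile yields 60378 edges.
    """
    index = EdgeIndex(profile.region_ids)
    vec = profile.matrix[np.triu_indices(profile.n_regions, k=1)]
    return vec, index


def devectorize_connectivity(
    edges: np.ndarray, index: EdgeIndex
) -> ConnectivityProfile:
    """Inverse of :func:`vectorize_connectivity` (unit diagonal restored)."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (len(index),):
        raise ValueError(
            f"edge vector length {edges.shape} does not match index length {len(index)}"
        )
    r = len(index.region_ids)
    mat = np.eye(r)
    iu = np.triu_indices(r, k=1)
    mat[iu] = edges
    mat[(iu[1], iu[0])] = edges
    return ConnectivityProfile(mat, index.region_ids)


def stack_profiles(
    profiles: dict[str, ConnectivityProfile]
) -> tuple[DataMatrix, EdgeIndex]:
    """Vectorize per-subject connectivity profiles into one subjects x edges matrix."""
    if not profiles:
        raise ValueError("no profiles supplied")
    subjects = list(profiles)
    first_vec, index = vectorize_connectivity(profiles[subjects[0]])
    rows = [first_vec]
    for sid in subjects[1:]:
        vec, idx = vectorize_connectivity(profiles[sid])
        if idx != index:
            raise ValueError(f"subject {sid} has different region_ids")
        rows.append(vec)
    return DataMatrix(np.vstack(rows), subjects, index.edge_ids()), index


# ---------------------------------------------------------------------------
# Alignment


def align_subjects(
    brain: DataMatrix, behaviour: DataMatrix, confounds: ConfoundTable
) -> DatasetBundle:
    """Restrict all inputs to their common subjects, in the brain view's order.

    Subjects missing from any input are dropped from all of them (and
    logged).  Raises if the intersection is empty.  Idempotent.
    """
    common = (
        set(brain.subject_ids) & set(behaviour.subject_ids) & set(confounds.subject_ids)
    )
    if not common:
        raise ValueError("no subjects common to brain, behaviour and confounds")
    order = [s for s in brain.subject_ids if s in common]
    for name, ids in (
        ("brain", brain.subject_ids),
        ("behaviour", behaviour.subject_ids),
        ("confounds", confounds.subject_ids),
    ):
        dropped = sorted(set(ids) - common)
        if dropped:
            logger.info("align_subjects: dropping %d subjects from %s: %s",
                        len(dropped), name, dropped)
    return DatasetBundle(
        brain.subset_subjects(order),
        behaviour.subset_subjects(order),
        confounds.subset_subjects(order),
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_data_matrix(path: str | Path, allow_missing: bool = False) -> DataMatrix:
    """Read a DataMatrix from CSV/TSV: header row of variable ids, first
    column of subject ids."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return DataMatrix.from_frame(frame, allow_missing=allow_missing)


def write_data_matrix(matrix: DataMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path), index_label="subject_id")


def read_confound_table(
    path: str | Path, site_levels: Sequence[str] | None = None
) -> ConfoundTable:
    """Read confounds from CSV/TSV with columns mean_fd, max_fd, site."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    required = {"mean_fd", "max_fd", "site"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"confound table missing columns: {sorted(missing)}")
    return ConfoundTable(
        list(frame.index.astype(str)),
        frame["mean_fd"].to_numpy(dtype=float),
        frame["max_fd"].to_numpy(dtype=float),
        list(frame["site"].astype(str)),
        list(site_levels) if site_levels is not None else [],
    )


def write_confound_table(table: ConfoundTable, path: str | Path) -> None:
    path = Path(path)
    table.to_frame().to_csv(path, sep=_sep_for(path), index_label="subject_id")


def read_connectivity_matrix(path: str | Path) -> ConnectivityProfile:
    """Read one subject's square connectivity matrix (region ids as header
    and first column)."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if list(frame.index.astype(str)) != list(frame.columns.astype(str)):
        raise ValueError("row and column region ids differ")
    return ConnectivityProfile(frame.to_numpy(dtype=float), list(frame.columns.astype(str)))


def read_region_metadata(path: str | Path) -> pd.DataFrame:
    """Region metadata TSV: region_id, network_label and optional x, y, z."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    if "region_id" not in frame.columns or "network_label" not in frame.columns:
        raise ValueError("region metadata needs region_id and network_label columns")
    frame["region_id"] = frame["region_id"].astype(str)
    if frame["region_id"].duplicated().any():
        raise ValueError("duplicate region_id in metadata")
    return frame


def write_edge_matrix_hdf5(matrix: DataMatrix, path: str | Path) -> None:
    """Store a stacked subjects x edges matrix in an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=matrix.values)
        f.create_dataset(
            "subject_ids", data=np.array(matrix.subject_ids, dtype="S")
        )
        f.create_dataset(
            "variable_ids", data=np.array(matrix.variable_ids, dtype="S")
        )


def read_edge_matrix_hdf5(path: str | Path) -> DataMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        return DataMatrix(
            f["values"][...],
            [s.decode() for s in f["subject_ids"][...]],
            [v.decode() for v in f["variable_ids"][...]],
        )
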