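"""Pedigree handling: numerator relationship matrix, inbreeding, status number.

The numerator relationship matrix ``A`` is built with the tabular (recursive)
method; unknown parents are treated as unrelated, non-inbred founders.  Group
coancestry and the status-number effective size ``N_S = 1 / (2 * theta)`` are
computed from any relationship kernel on the A scale (coancestry = kinship =
relationship / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNKNOWN_PARENT",
    "PedigreeError",
    "Pedigree",
    "RelationshipMatrix",
    "CoancestrySummary",
    "build_A",
    "inbreeding",
    "status_number",
]

#: sentinel id for an unknown parent in pedigree files
UNKNOWN_PARENT = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id, missing parent)."""


def _norm_id(x) -> str:
    if x is None:
        return UNKNOWN_PARENT
    if isinstance(x, float):
        if np.isnan(x):
            return UNKNOWN_PARENT
        if x.is_integer():
            x = int(x)
    s = str(x).strip()
    return s if s else UNKNOWN_PARENT


@dataclass
class Pedigree:
    """Ordered (id, sire, dam) records; unknown parent encoded as ``"0"``.

    Records may arrive in any order; a topological sort is performed
    internally.  Construction validates uniqueness and acyclicity.
    """

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = [
            (_norm_id(i), _norm_id(s), _norm_id(d)) for i, s, d in self.records
        ]
        ids = [r[0] for r in self.records]
        if UNKNOWN_PARENT in ids:
            raise PedigreeError(f"individual id {UNKNOWN_PARENT!r} is reserved for unknown parents")
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise PedigreeError(f"duplicate individual id {i!r}")
            seen.add(i)
        self._order = self._toposort()

    # -- basic accessors ---------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [r[0] for r in self.records]

    def parents(self, ind: str) -> tuple[str, str]:
        for i, s, d in self.records:
            if i == ind:
                return s, d
        raise KeyError(ind)

    def __len__(self) -> int:
        return len(self.records)

    # -- structure ---------------------------------------------------------
    def _toposort(self) -> list[str]:
        """Kahn's algorithm; raises PedigreeError naming a cycle member."""
        parent_of = {i: [p for p in (s, d) if p != UNKNOWN_PARENT] for i, s, d in self.records}
        known = set(parent_of)
        # parents never listed as individuals are implicit founders
        for ps in list(parent_of.values()):
            for p in ps:
                if p not in known:
                    parent_of[p] = []
        indeg = {i: 0 for i in parent_of}
        children: dict[str, list[str]] = {i: [] for i in parent_of}
        for i, ps in parent_of.items():
            indeg[i] = len(ps)
            for p in ps:
                children[p].append(i)
        queue = sorted(i for i, d in indeg.items() if d == 0)
        order: list[str] = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for c in children[n]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(parent_of):
            cycle = sorted(i for i, d in indeg.items() if d > 0)
            raise PedigreeError(f"pedigree contains a cycle involving: {', '.join(cycle)}")
        return order

    def topological_ids(self) -> list[str]:
        """All ids (including implicit founders), parents before offspring."""
        return list(self._order)

    # -- IO helpers --------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        cols = {c.lower(): c for c in df.columns}
        for need in ("id", "sire", "dam"):
            if need not in cols:
                raise PedigreeError(f"pedigree table missing column {need!r}")
        recs = [
            (row[cols["id"]], row[cols["sire"]], row[cols["dam"]])
            for _, row in df.iterrows()
        ]
        return cls(recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["id", "sire", "dam"])


@dataclass
class RelationshipMatrix:
    """Labelled symmetric relationship kernel, kind 'A' (pedigree) or 'G' (genomic)."""

    labels: list[str]
    values: np.ndarray
    kind: str = "A"

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if self.kind not in ("A", "G"):
            raise ValueError(f"kind must be 'A' or 'G', got {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("relationship matrix is not symmetric")

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {l: k for k, l in enumerate(self.labels)}
        missing = [str(i) for i in ids if str(i) not in pos]
        if missing:
            raise KeyError(f"ids not in relationship matrix: {missing[:10]}")
        return np.array([pos[str(i)] for i in ids], dtype=int)

    def subset(self, ids: Sequence[str]) -> "RelationshipMatrix":
        idx = self.index_of(ids)
        return RelationshipMatrix(
            [str(i) for i in ids], self.values[np.ix_(idx, idx)], kind=self.kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class CoancestrySummary:
    theta: float
    status_number: float
    n_individuals: int


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``A[i, j] = (A[j, sire(i)] + A[j, dam(i)]) / 2`` for previously processed
    ``j`` and ``A[i, i] = 1 + A[sire(i), dam(i)] / 2``; unknown parents
    contribute zero.
    """
    order = ped.topological_ids()
    pos = {ind: k for k, ind in enumerate(order)}
    parents = {i: (s, d) for i, s, d in ped.records}
    n = len(order)
    A = np.zeros((n, n))
    for k, ind in enumerate(order):
        s, d = parents.get(ind, (UNKNOWN_PARENT, UNKNOWN_PARENT))
        si = pos[s] if s != UNKNOWN_PARENT else None
        di = pos[d] if d != UNKNOWN_PARENT else None
        row = np.zeros(k)
        if si is not None:
            row += 0.5 * A[si, :k]
        if di is not None:
            row += 0.5 * A[di, :k]
        A[k, :k] = row
        A[:k, k] = row
        f = 0.5 * A[si, di] if (si is not None and di is not None) else 0.0
        A[k, k] = 1.0 + f
    return RelationshipMatrix(order, A, kind="A")


def inbreeding(K: RelationshipMatrix) -> pd.Series:
    """Per-individual inbreeding coefficient ``F_i = K_ii - 1``.

    For a genomic kernel the diagonal-based value is returned too, but it is a
    realized (marker) statistic, not pedigree inbreeding; a warning says so.
    """
    if K.kind == "G":
        warnings.warn(
            "inbreeding() on a genomic kernel returns realized marker-based "
            "values, not pedigree inbreeding",
            stacklevel=2,
        )
    return pd.Series(np.diag(K.values) - 1.0, index=K.labels, name="F")


def status_number(K: RelationshipMatrix, subset: Iterable[str]) -> CoancestrySummary:
    """Status-number effective size of an equally-weighted group.

    Group coancestry ``theta = sum_ij K_ij / (2 N^2)`` (relationship / 2 is
    coancestry, averaged over all N^2 ordered pairs including self pairs);
    ``N_S = 1 / (2 theta)``.  N unrelated non-inbred individuals give
    ``N_S = N`` exactly.
    """
    ids = [str(i) for i in subset]
    if not ids:
        raise ValueError("status_number: empty subset")
    idx = K.index_of(ids)
    n = len(ids)
    theta = float(K.values[np.ix_(idx, idx)].sum()) / (2.0 * n * n)
    if theta <= 0:
        raise ValueError(f"non-positive group coancestry ({theta}); invalid kernel")
    return CoancestrySummary(theta=theta, status_number=1.0 / (2.0 * theta), n_individuals=n)
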