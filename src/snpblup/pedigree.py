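"""Pedigree handling and the pedigree-based (PB) additive relationship matrix.

The additive (numerator) relationship matrix ``A`` is built with the tabular
method: processing animals with parents before offspring,

    a_kk = 1 + 0.5 * a(sire_k, dam_k)
    a_jk = 0.5 * (a(j, sire_k) + a(j, dam_k))   for j earlier than k,

with unknown parents contributing 0.  The diagonal is 1 + F_k where F_k is the
inbreeding coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import PedigreeError
from .relmat import RelationshipMatrix

UNKNOWN = "0"


@dataclass(frozen=True)
class Pedigree:
    """Individual records with sire/dam links.

    ``ids`` are unique strings; ``sires``/``dams`` hold the parent id or
    :data:`UNKNOWN` (``"0"``).  Record order is meaningful: the tabular method
    requires parents before offspring (see :func:`sort_pedigree`).
    """

    ids: tuple[str, ...]
    sires: tuple[str, ...]
    dams: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dup = pd.Series(self.ids)
            raise PedigreeError(
                f"duplicate ids: {sorted(dup[dup.duplicated()].unique())}"
            )
        if not (len(self.ids) == len(self.sires) == len(self.dams)):
            raise PedigreeError("ids, sires and dams must have equal length")
        known = set(self.ids)
        for parent in set(self.sires) | set(self.dams):
            if parent != UNKNOWN and parent not in known:
                raise PedigreeError(f"parent {parent!r} has no record of its own")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def parents(self, individual: str) -> tuple[str, str]:
        k = self.index[individual]
        return self.sires[k], self.dams[k]

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str | None, str | None]]
    ) -> "Pedigree":
        ids, sires, dams = [], [], []
        for rid, s, d in records:
            ids.append(str(rid))
            sires.append(UNKNOWN if s in (None, "", UNKNOWN) else str(s))
            dams.append(UNKNOWN if d in (None, "", UNKNOWN) else str(d))
        return cls(tuple(ids), tuple(sires), tuple(dams))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        missing = {"id", "sire", "dam"} - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns: {sorted(missing)}")
        return cls.from_records(
            zip(df["id"].astype(str), df["sire"].astype(str), df["dam"].astype(str))
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "sire": self.sires, "dam": self.dams})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def full_sib_families(self) -> dict[tuple[str, str], list[str]]:
        """Group individuals by (sire, dam); both parents must be known."""
        fams: dict[tuple[str, str], list[str]] = {}
        for i, s, d in zip(self.ids, self.sires, self.dams):
            if s != UNKNOWN and d != UNKNOWN:
                fams.setdefault((s, d), []).append(i)
        return fams


def is_sorted(ped: Pedigree) -> bool:
    """True if every parent appears before its offspring."""
    pos = ped.index
    return all(
        (s == UNKNOWN or pos[s] < k) and (d == UNKNOWN or pos[d] < k)
        for k, (s, d) in enumerate(zip(ped.sires, ped.dams))
    )


def sort_pedigree(ped: Pedigree) -> Pedigree:
    """Topologically sort so parents precede offspring.

    Stable: ties are broken by input order (an already-sorted pedigree is
    returned in identical order).  A parent cycle raises
    :class:`~snpblup.errors.PedigreeError` naming an individual on the cycle.
    """
    pos = ped.index
    n = len(ped)
    children: list[list[int]] = [[] for _ in range(n)]
    n_pending = np.zeros(n, dtype=int)
    for k, (s, d) in enumerate(zip(ped.sires, ped.dams)):
        for p in {s, d} - {UNKNOWN}:
            children[pos[p]].append(k)
            n_pending[k] += 1
    # Kahn's algorithm with a sorted ready-set keyed on input position.
    import heapq

    ready = [k for k in range(n) if n_pending[k] == 0]
    heapq.heapify(ready)
    order: list[int] = []
    while ready:
        k = heapq.heappop(ready)
        order.append(k)
        for c in children[k]:
            n_pending[c] -= 1
            if n_pending[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != n:
        stuck = next(ped.ids[k] for k in range(n) if n_pending[k] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving {stuck!r}")
    return Pedigree(
        tuple(ped.ids[k] for k in order),
        tuple(ped.sires[k] for k in order),
        tuple(ped.dams[k] for k in order),
    )


def additive_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Additive relationship matrix from a sorted pedigree (tabular method)."""
    if not is_sorted(ped):
        raise PedigreeError(
            "pedigree is not sorted (parents must precede offspring); "
            "call sort_pedigree first"
        )
    n = len(ped)
    pos = ped.index
    a = np.zeros((n, n))
    for k in range(n):
        s, d = ped.sires[k], ped.dams[k]
        si = pos[s] if s != UNKNOWN else -1
        di = pos[d] if d != UNKNOWN else -1
        row = np.zeros(k)
        if si >= 0:
            row += a[si, :k]
        if di >= 0:
            row += a[di, :k]
        a[k, :k] = 0.5 * row
        a[:k, k] = a[k, :k]
        a[k, k] = 1.0 + (0.5 * a[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(labels=list(ped.ids), values=a, method="PB")


def inbreeding(A: RelationshipMatrix) -> pd.Series:
    """Per-individual inbreeding coefficient F_i = a_ii - 1."""
    return pd.Series(np.diag(A.values) - 1.0, index=A.labels, name="F")


def selfcoancestry_diagonal(parent_relationship: float) -> float:
    """Diagonal (selfcoancestry) value from the parents' relationship.

    ``F_k = 1 + 0.5 * a_ij`` where ``a_ij`` is the relationship between the
    parents of ``k``; an unknown parent contributes ``a_ij = 0``.
    """
    return 1.0 + 0.5 * parent_relationship
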