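"""Genetic relationship (covariance) matrices.

A :class:`RelationshipMatrix` is the common currency of the package: the
pedigree-based additive relationship matrix, the Loiselle marker estimator and
the averaged local genomic relationship all produce one, and the animal model
consumes one.  Matrices are stored dense (desk scale: a few thousand animals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, FormatError


@dataclass
class RelationshipMatrix:
    """Symmetric individuals x individuals genetic covariance structure.

    Parameters
    ----------
    labels
        Individual ids, fixing row/column order.
    values
        Symmetric ``(n, n)`` array.  ``NaN`` on the diagonal marks entries a
        marker estimator left blank (to be filled from parental relationships).
    method
        Provenance tag, e.g. ``"PB"``, ``"SNPL"``, ``"SNPC"``.
    bend_shift
        Total diagonal shift applied by :func:`bend_to_pd` (0 if never bent).
    """

    labels: list[str]
    values: np.ndarray
    method: str = ""
    bend_shift: float = 0.0
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.values[off], self.values.T[off], equal_nan=True):
            raise FormatError("relationship matrix must be symmetric")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != n:
            raise FormatError("duplicate labels in relationship matrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[lab] for lab in labels], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise FormatError(f"label {e.args[0]!r} not in relationship matrix")

    def submatrix(self, labels: Sequence[str]) -> np.ndarray:
        idx = self.indices(labels)
        return self.values[np.ix_(idx, idx)]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())

    @property
    def is_pd(self) -> bool:
        return self.min_eigenvalue() > 0.0

    # ---- plain-text I/O: full matrix, id header row and leading id column ----

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("id " + " ".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.values):
                fh.write(lab + " " + " ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def read(cls, path: str | Path, method: str = "") -> "RelationshipMatrix":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline().split()
            if not header or header[0] != "id":
                raise FormatError(f"{path}: expected 'id' header row")
            labels = header[1:]
            rows, row_labels = [], []
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                row_labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if row_labels != labels:
            raise FormatError(f"{path}: row labels do not match header labels")
        values = np.array(rows, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise FormatError(f"{path}: ragged or non-square matrix")
        return cls(labels=labels, values=values, method=method)


def read_ibd_matrices(paths: Sequence[str | Path]) -> list[RelationshipMatrix]:
    """Read externally computed per-position IBD matrices.

    All files must parse to conformable matrices with identical labels,
    suitable for :func:`snpblup.markers.local_relationship_average` /
    elementwise averaging.
    """
    if not paths:
        raise ConfigError("no IBD matrix files supplied")
    mats = [RelationshipMatrix.read(p) for p in paths]
    ref = mats[0].labels
    for p, m in zip(paths, mats):
        if m.labels != ref:
            raise FormatError(f"{p}: labels differ from first matrix")
    return mats


def bend_to_pd(M: RelationshipMatrix, epsilon: float = 1e-6) -> RelationshipMatrix:
    """Make a relationship matrix safely positive definite.

    If the minimum eigenvalue is below ``epsilon``, add ``epsilon - lambda_min``
    to every diagonal element (minimal uniform diagonal inflation).  The applied
    shift is recorded in ``bend_shift``.  A matrix already satisfying
    ``lambda_min >= epsilon`` is returned unchanged.
    """
    if epsilon <= 0:
        raise ConfigError("bending epsilon must be positive")
    if np.isnan(M.values).any():
        raise FormatError("matrix has blank entries; fill the diagonal first")
    lam = M.min_eigenvalue()
    if lam >= epsilon:
        return M
    shift = epsilon - lam
    values = M.values + shift * np.eye(M.n)
    return replace(M, values=values, bend_shift=M.bend_shift + shift)
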