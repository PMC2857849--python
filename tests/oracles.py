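"""Independent oracles used by the test suite.

Deliberately naive implementations, kept separate from the package code
paths they validate: recursive coancestry for the additive relationship
matrix, a literal per-allele / per-chromosome-copy evaluation of the
Loiselle estimator, and the closed-form GLS conditional-expectation BLUP.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from snpblup.pedigree import UNKNOWN, Pedigree


def kinship_matrix(ped: Pedigree) -> np.ndarray:
    """Coancestry (kinship) matrix by memoised recursion; A = 2 * kinship."""
    pos = ped.index

    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        # j is never an ancestor of i when j >= i in a sorted pedigree
        s, d = ped.sires[j], ped.dams[j]
        fs = f(i, pos[s]) if s != UNKNOWN else 0.0
        fd = f(i, pos[d]) if d != UNKNOWN else 0.0
        if i == j:
            return 0.5 * (1.0 + (f(pos[s], pos[d]) if UNKNOWN not in (s, d) else 0.0))
        return 0.5 * (fs + fd)

    n = len(ped)
    K = np.array([[f(i, j) for j in range(n)] for i in range(n)])
    return K


def loiselle_naive(counts: np.ndarray) -> np.ndarray:
    """Quadruple-loop Loiselle estimator (complete data, biallelic).

    Expands each genotype into two chromosome copies carrying 0/1 indicator
    variables per allele, then sums the cross-products of indicator
    deviations over loci, both alleles and the 2x2 copy pairs, adds the
    per-locus 1/(n_l - 1) bias term, and divides by the total
    sum_l sum_a p_a (1 - p_a).  Diagonal is NaN (pairwise estimator).
    """
    n, L = counts.shape
    n_l = 2 * n
    p1 = counts.sum(axis=0) / n_l  # counted-allele frequency per locus

    def copies(g: float) -> list[int]:
        return {0.0: [0, 0], 1.0: [1, 0], 2.0: [1, 1]}[g]

    denom = 0.0
    for l in range(L):
        for p_a in (p1[l], 1.0 - p1[l]):
            denom += p_a * (1.0 - p_a)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = 0.0
            for l in range(L):
                for allele in (1, 0):
                    p_a = p1[l] if allele == 1 else 1.0 - p1[l]
                    xi = [1 if c == allele else 0 for c in copies(counts[i, l])]
                    xj = [1 if c == allele else 0 for c in copies(counts[j, l])]
                    cross = 0.0
                    for ci in range(2):
                        for cj in range(2):
                            cross += (xi[ci] - p_a) * (xj[cj] - p_a)
                    num += cross / 4.0
                    num += p_a * (1.0 - p_a) / (n_l - 1)
            out[i, j] = num / denom
    return out


def gls_blup(
    G: np.ndarray, pheno_idx: np.ndarray, y: np.ndarray, sa: float, se: float
) -> tuple[float, np.ndarray]:
    """Closed-form GLS / conditional-expectation animal-model solution."""
    Gp = G[np.ix_(pheno_idx, pheno_idx)]
    V = sa * Gp + se * np.eye(len(y))
    Vi = np.linalg.inv(V)
    one = np.ones(len(y))
    mu = float(one @ Vi @ y / (one @ Vi @ one))
    a = sa * G[:, pheno_idx] @ Vi @ (y - mu * one)
    return mu, a
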