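"""Marker-based relationship matrices.

Two estimators are provided:

* :func:`loiselle_relatedness` — the Loiselle moment estimator of pairwise
  relationship from allele-frequency deviations, with the 1/(n_l - 1)
  sampling-bias correction.  It leaves the diagonal blank, mirroring how the
  estimator is defined pair-wise; :func:`fill_diagonal` completes it from the
  marker relationship of each individual's parents
  (``a_kk = 1 + 0.5 * m(sire_k, dam_k)``).
* :func:`local_relationship_average` — a deterministic stand-in for
  MCMC-sampled locus-specific IBD matrices: a windowed local genomic
  relationship (VanRaden-type cross-product of centred allele counts over the
  loci nearest each evaluation point) computed at ``n_points`` equally spaced
  positions and averaged elementwise into one G-matrix.  Externally computed
  per-position IBD matrices can be substituted via
  :func:`snpblup.relmat.read_ibd_matrices` + :func:`average_matrices`.

For a biallelic locus with counted-allele frequency ``p`` and genotype counts
``g_i``, the Loiselle numerator contribution reduces to

    (g_i - 2p) (g_j - 2p) / 2  +  2 p (1 - p) / (n_l - 1)

summed over loci (the per-allele sum runs over both alleles, whose terms are
equal), and the denominator is ``sum_l 2 p_l (1 - p_l)``.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, DataError, NumericalError
from .genotypes import AlleleFrequencies, GenotypeMatrix, allele_frequencies
from .pedigree import UNKNOWN, Pedigree
from .relmat import RelationshipMatrix


def loiselle_relatedness(
    G: GenotypeMatrix, freqs: AlleleFrequencies | None = None
) -> RelationshipMatrix:
    """Pairwise Loiselle relationship; diagonal left blank (NaN).

    Frequencies and defined-allele counts always come from the full reference
    sample; loci with a missing call in either member of a pair are excluded
    from that pair's numerator.
    """
    if G.n_individuals < 2:
        raise DataError("need at least 2 individuals")
    if freqs is None:
        freqs = allele_frequencies(G)
    p = freqs.p
    nl = freqs.n_alleles.astype(float)
    if (nl < 2).any():
        raise DataError("every locus needs at least 2 defined allele copies")
    pq2 = 2.0 * p * (1.0 - p)  # sum over both alleles of p_a (1 - p_a)
    denom = pq2.sum()
    if denom <= 0.0:
        raise NumericalError("all loci monomorphic: zero denominator")
    obs = (~G.missing).astype(float)
    dev = np.where(G.missing, 0.0, G.counts - 2.0 * p)
    cross = dev @ dev.T / 2.0
    bias = pq2 / (nl - 1.0)
    pair_bias = obs @ (obs * bias).T  # locus bias counted only when both typed
    values = (cross + pair_bias) / denom
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, np.nan)
    return RelationshipMatrix(labels=list(G.ids), values=values, method="SNPL")


def fill_diagonal(M: RelationshipMatrix, ped: Pedigree) -> RelationshipMatrix:
    """Complete a blank-diagonal marker matrix from parental relationships.

    The selfcoancestry of individual ``k`` is ``1 + 0.5 * m(sire_k, dam_k)``
    with ``m`` the marker-based relationship between its parents; when either
    parent is unknown or not genotyped the diagonal defaults to 1.
    """
    pos = ped.index
    for lab in M.labels:
        if lab not in pos:
            raise DataError(f"individual {lab!r} missing from pedigree")
    values = M.values.copy()
    in_matrix = set(M.labels)
    for k, lab in enumerate(M.labels):
        s, d = ped.parents(lab)
        if s != UNKNOWN and d != UNKNOWN and s in in_matrix and d in in_matrix:
            values[k, k] = 1.0 + 0.5 * M.loc(s, d)
        else:
            values[k, k] = 1.0
    return RelationshipMatrix(
        labels=list(M.labels), values=values, method=M.method
    )


def _local_grm(
    dev: np.ndarray, pq2: np.ndarray, window: np.ndarray
) -> np.ndarray:
    d = dev[:, window]
    scale = pq2[window].sum()
    if scale <= 0.0:
        raise NumericalError("window contains only monomorphic loci")
    return d @ d.T / scale


def local_relationship_average(
    G: GenotypeMatrix,
    n_points: int = 9,
    window_loci: int | None = None,
) -> RelationshipMatrix:
    """Average of local genomic relationship matrices at ``n_points`` positions.

    Evaluation points are equally spaced over the position span of the panel;
    the matrix at each point uses the ``window_loci`` map-nearest loci
    (default ``max(10, ceil(L / n_points))``, capped at ``L``).  The result is
    the elementwise mean of the per-position matrices, diagonal included.
    """
    if n_points < 1:
        raise ConfigError("n_points must be >= 1")
    L = G.n_loci
    if L < n_points:
        raise DataError(f"only {L} loci after filtering; need >= {n_points}")
    if window_loci is None:
        window_loci = max(10, int(np.ceil(L / n_points)))
    window_loci = min(window_loci, L)
    freqs = allele_frequencies(G)
    p = freqs.p
    pq2 = 2.0 * p * (1.0 - p)
    dev = np.where(G.missing, 0.0, G.counts - 2.0 * p)
    pos = G.loci["position_morgans"].to_numpy(dtype=float)
    points = (
        np.linspace(pos.min(), pos.max(), n_points)
        if n_points > 1
        else np.array([(pos.min() + pos.max()) / 2.0])
    )
    acc = np.zeros((G.n_individuals, G.n_individuals))
    for x in points:
        nearest = np.argsort(np.abs(pos - x), kind="stable")[:window_loci]
        acc += _local_grm(dev, pq2, np.sort(nearest))
    values = acc / n_points
    values = 0.5 * (values + values.T)
    return RelationshipMatrix(labels=list(G.ids), values=values, method="SNPC")


def average_matrices(mats: list[RelationshipMatrix]) -> RelationshipMatrix:
    """Elementwise mean of conformable relationship matrices."""
    if not mats:
        raise ConfigError("no matrices to average")
    ref = mats[0].labels
    for m in mats[1:]:
        if m.labels != ref:
            raise DataError("matrices have mismatched labels")
    values = np.mean([m.values for m in mats], axis=0)
    return RelationshipMatrix(
        labels=list(ref), values=values, method=mats[0].method
    )
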