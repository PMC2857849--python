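"""SNP genotype container, allele frequencies and panel filtering.

Genotypes are diploid minor-allele counts in {0, 1, 2}; missing calls are
``NaN``.  Loci are kept sorted by chromosome then position (Morgans).

File formats (plain text):

* genotype file — whitespace separated, one row per individual, first column
  the id, then one 0/1/2 count per locus, ``NA`` for missing;
* map file — whitespace separated with header
  ``chromosome snp_id position_morgans``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError


@dataclass
class GenotypeMatrix:
    """individuals x loci allele-count matrix with a locus map."""

    ids: list[str]
    loci: pd.DataFrame  # columns: chromosome, snp_id, position_morgans
    counts: np.ndarray  # (n, L) float; values 0/1/2 or NaN

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n, L = self.counts.shape
        if n != len(self.ids):
            raise FormatError("genotype rows do not match ids")
        if L != len(self.loci):
            raise FormatError("genotype columns do not match locus map")
        ok = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not ok.all():
            raise DataError("genotype counts must be 0, 1, 2 or missing")
        chrom = self.loci["chromosome"].astype(str).to_numpy()
        pos = self.loci["position_morgans"].to_numpy(dtype=float)
        order = np.lexsort((pos, chrom))
        if not (order == np.arange(L)).all():
            self.loci = self.loci.iloc[order].reset_index(drop=True)
            self.counts = self.counts[:, order]

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_loci(self) -> int:
        return self.counts.shape[1]

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.counts)

    def take_loci(self, which: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            ids=list(self.ids),
            loci=self.loci.iloc[which].reset_index(drop=True),
            counts=self.counts[:, which],
        )

    # ---------------------------- plain-text I/O ----------------------------

    def write(self, genotype_path: str | Path, map_path: str | Path) -> None:
        with Path(genotype_path).open("w") as fh:
            for rid, row in zip(self.ids, self.counts):
                cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
                fh.write(rid + " " + " ".join(cells) + "\n")
        self.loci.to_csv(map_path, sep=" ", index=False)

    @classmethod
    def read(
        cls, genotype_path: str | Path, map_path: str | Path
    ) -> "GenotypeMatrix":
        loci = pd.read_csv(map_path, sep=r"\s+")
        need = {"chromosome", "snp_id", "position_morgans"}
        if not need <= set(loci.columns):
            raise FormatError(f"{map_path}: expected columns {sorted(need)}")
        loci["chromosome"] = loci["chromosome"].astype(str)
        loci["snp_id"] = loci["snp_id"].astype(str)
        ids, rows = [], []
        with Path(genotype_path).open() as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                ids.append(parts[0])
                rows.append(
                    [np.nan if c == "NA" else float(c) for c in parts[1:]]
                )
        counts = np.array(rows, dtype=float)
        return cls(ids=ids, loci=loci, counts=counts)


@dataclass(frozen=True)
class AlleleFrequencies:
    """Per-locus frequency of the counted allele and defined-allele count.

    ``n_alleles`` at a locus is the number of individuals times the ploidy (2)
    minus the number of missing allele copies.
    """

    p: np.ndarray  # frequency of the counted allele per locus
    n_alleles: np.ndarray  # defined allele copies per locus

    def __post_init__(self) -> None:
        if ((self.p < 0) | (self.p > 1)).any():
            raise DataError("allele frequencies must lie in [0, 1]")


def allele_frequencies(G: GenotypeMatrix) -> AlleleFrequencies:
    """Counted-allele frequency per locus over the full reference sample."""
    obs = ~G.missing
    n_alleles = 2 * obs.sum(axis=0)
    if (n_alleles == 0).any():
        bad = G.loci.loc[n_alleles == 0, "snp_id"].tolist()
        raise DataError(f"loci with all calls missing (drop them first): {bad}")
    p = np.nansum(G.counts, axis=0) / n_alleles
    return AlleleFrequencies(p=p, n_alleles=n_alleles.astype(int))


def maf_filter(G: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Retain loci with minor allele frequency strictly above ``threshold``."""
    freqs = allele_frequencies(G)
    maf = np.minimum(freqs.p, 1.0 - freqs.p)
    keep = np.flatnonzero(maf > threshold)
    if keep.size == 0:
        raise DataError(f"no loci with MAF > {threshold}: empty panel")
    return G.take_loci(keep)


def subset_chromosome(G: GenotypeMatrix, chromosome: str) -> GenotypeMatrix:
    """Restrict the panel to one chromosome (ids unchanged)."""
    chrom = str(chromosome)
    keep = np.flatnonzero(G.loci["chromosome"].astype(str) == chrom)
    if keep.size == 0:
        present = sorted(G.loci["chromosome"].astype(str).unique())
        raise DataError(f"chromosome {chrom!r} not in panel (have {present})")
    return G.take_loci(keep)
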