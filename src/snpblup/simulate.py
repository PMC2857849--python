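"""Synthetic multi-generation populations with a quadratic longitudinal trait.

The generator produces the study conditions the rest of the package assumes:

* a discrete-generation pedigree of full-sib families (random pairing within
  each generation, fixed family size, alternating sexes);
* biallelic SNPs on several chromosomes, founder allele frequencies drawn
  from Uniform(0.05, 0.5), offspring genotypes by gene dropping with
  Haldane-model recombination (no interference; crossover probability between
  adjacent loci ``r = (1 - exp(-2d)) / 2`` for map distance ``d`` Morgans);
* a subset of panel loci act as QTLs whose allelic effects act additively on
  each animal's *trajectory coefficients* (beta0, beta1, beta2), so the true
  breeding value ``bv_i(t) = beta0_i + beta1_i t + beta2_i t^2`` is exactly
  quadratic in time — quadratic extrapolation of true values to an unobserved
  time is exact by construction, isolating downstream prediction error to EBV
  estimation;
* a stated fraction of trajectory-coefficient variance comes from
  chromosome-1 QTLs (the chromosome carrying the large effects);
* phenotypes ``y = mean(t) + bv_i(t) + e`` at each recorded time point, with
  residual variance per time point scaled to the realised genetic variance so
  heritability stays ~constant while both variances grow with time;
* validation animals (drawn from the final generation) carry no phenotype
  records; their true breeding values at every time point, including the
  held-out time, are retained for evaluation.

All randomness flows from one seeded :class:`numpy.random.Generator`, so a
given configuration is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genotypes import GenotypeMatrix
from .pedigree import UNKNOWN, Pedigree

# Trajectory-coefficient variances targeted among all animals.  Chosen so the
# genetic variance of bv(t) grows from ~0.05 at t=0 to ~19 at t=530, the
# magnitude pattern of a growth-like trait recorded over ~500 time units.
COEF_VARIANCES = (0.05, 2.5e-5, 1.5e-10)

# Population mean trajectory (fixed, non-genetic part of the phenotype).
MEAN_CURVE = (2.0, 0.03, 1.0e-5)


def mean_curve(t: float) -> float:
    b0, b1, b2 = MEAN_CURVE
    return b0 + b1 * t + b2 * t * t


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic population."""

    n_founders: int = 40
    n_generations: int = 3  # founder generation + descendant generations
    offspring_per_mating: int = 10
    n_chromosomes: int = 5
    snps_per_chromosome: int = 100
    chromosome_length_morgans: float = 1.0
    n_qtl: int = 30
    fraction_qtl_variance_on_chr1: float = 0.7
    time_points: tuple[float, ...] = (0.0, 132.0, 265.0, 397.0, 530.0)
    holdout_time: float = 600.0
    target_heritability: float = 0.5
    n_validation_unphenotyped: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_founders": self.n_founders,
            "n_generations": self.n_generations,
            "offspring_per_mating": self.offspring_per_mating,
            "n_chromosomes": self.n_chromosomes,
            "snps_per_chromosome": self.snps_per_chromosome,
            "n_validation_unphenotyped": self.n_validation_unphenotyped,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.n_founders % 2:
            raise ConfigError("n_founders must be even (half sires, half dams)")
        if self.n_generations < 2:
            raise ConfigError("need at least one descendant generation")
        if self.chromosome_length_morgans <= 0:
            raise ConfigError("chromosome length must be positive")
        if self.n_qtl < 0 or self.n_qtl > self.n_loci:
            raise ConfigError(
                f"n_qtl must be in [0, {self.n_loci}], got {self.n_qtl}"
            )
        f = self.fraction_qtl_variance_on_chr1
        if not 0.0 <= f <= 1.0:
            raise ConfigError(f"fraction_qtl_variance_on_chr1 must be in [0, 1]")
        if not 0.0 < self.target_heritability < 1.0:
            raise ConfigError("target_heritability must be in (0, 1)")
        times = self.time_points
        if len(times) < 1 or any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError("time_points must be strictly increasing")
        if self.holdout_time <= times[-1]:
            raise ConfigError("holdout_time must exceed the last time point")
        if self.n_validation_unphenotyped > self.final_generation_size:
            raise ConfigError(
                f"n_validation_unphenotyped={self.n_validation_unphenotyped} "
                f"exceeds final generation size {self.final_generation_size}"
            )

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome

    @property
    def generation_sizes(self) -> list[int]:
        sizes = [self.n_founders]
        for _ in range(self.n_generations - 1):
            sizes.append((sizes[-1] // 2) * self.offspring_per_mating)
        return sizes

    @property
    def final_generation_size(self) -> int:
        return self.generation_sizes[-1]

    @property
    def all_times(self) -> tuple[float, ...]:
        return tuple(self.time_points) + (self.holdout_time,)


@dataclass
class TruePopulation:
    """A simulated population; truth retained where available.

    Populations read back from disk lack ``config``, ``qtl_effects`` and
    ``founder_origin`` (not serialised).
    """

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # long: id, time, value (masked ids absent)
    true_bv: pd.DataFrame  # index id, one column per time (incl. holdout)
    masked_ids: list[str]
    generation: pd.Series  # generation number per id
    config: SimulationConfig | None = None
    qtl_effects: pd.DataFrame | None = None  # snp_id, chromosome, alpha0..2
    founder_origin: np.ndarray | None = None  # (n, L, 2) founder-copy labels
    haplotypes: np.ndarray | None = None  # (n, L, 2) phased alleles

    @property
    def phenotyped_ids(self) -> list[str]:
        masked = set(self.masked_ids)
        return [i for i in self.pedigree.ids if i not in masked]


def _haldane_r(d: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * d))


def _gamete_strands(
    rng: np.random.Generator, n: int, switch_p: np.ndarray
) -> np.ndarray:
    """Parental-strand choice (0/1) per gamete and locus, Haldane model.

    ``switch_p[l]`` is the probability of a strand switch between locus
    ``l-1`` and ``l`` (0.5 at chromosome starts: independent segregation).
    """
    switch = rng.random((n, len(switch_p))) < switch_p[None, :]
    switch[:, 0] = rng.random(n) < 0.5  # random starting strand
    return np.cumsum(switch, axis=1) % 2


def _pick(hap: np.ndarray, strand: np.ndarray) -> np.ndarray:
    """Select one allele per locus from (n, L, 2) using strand (n, L)."""
    return np.take_along_axis(hap, strand[:, :, None], axis=2)[:, :, 0]


def _qtl_indices(
    rng: np.random.Generator, config: SimulationConfig, chrom: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split QTL loci between chromosome 1 and the rest."""
    n_qtl = config.n_qtl
    f = config.fraction_qtl_variance_on_chr1
    chr1 = np.flatnonzero(chrom == 1)
    other = np.flatnonzero(chrom != 1)
    if config.n_chromosomes == 1 or f >= 1.0:
        m1 = n_qtl
    elif f <= 0.0:
        m1 = 0
    else:
        m1 = int(np.clip(round(n_qtl * f), 1, n_qtl - 1))
    if m1 > len(chr1) or (n_qtl - m1) > len(other):
        raise ConfigError(
            f"cannot place {m1} QTLs on chromosome 1 ({len(chr1)} loci) and "
            f"{n_qtl - m1} elsewhere ({len(other)} loci)"
        )
    q1 = np.sort(rng.choice(chr1, size=m1, replace=False))
    q2 = np.sort(rng.choice(other, size=n_qtl - m1, replace=False))
    return q1, q2


def _scaled(u: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Rescale a centred vector to a target sample variance (factor returned)."""
    v = float(np.var(u, ddof=1)) if len(u) > 1 else 0.0
    if v <= 0.0 or target_var <= 0.0:
        return np.zeros_like(u), 0.0
    c = np.sqrt(target_var / v)
    return u * c, c


def simulate_population(config: SimulationConfig) -> TruePopulation:
    """Generate a population from a validated configuration (deterministic)."""
    rng = np.random.default_rng(config.seed)
    L = config.n_loci
    nC, nS = config.n_chromosomes, config.snps_per_chromosome

    # Locus map: equally spaced along each chromosome.
    pos_1 = np.linspace(0.0, config.chromosome_length_morgans, nS)
    chrom = np.repeat(np.arange(1, nC + 1), nS)
    pos = np.tile(pos_1, nC)
    loci = pd.DataFrame(
        {
            "chromosome": chrom.astype(str),
            "snp_id": [
                f"snp{c}_{k + 1}"
                for c, k in zip(chrom, np.tile(np.arange(nS), nC))
            ],
            "position_morgans": pos,
        }
    )
    gaps = np.diff(pos, prepend=pos[0])
    switch_p = _haldane_r(np.maximum(gaps, 0.0))
    switch_p[np.flatnonzero(np.diff(chrom, prepend=chrom[0]))] = 0.5
    switch_p[0] = 0.5

    sizes = config.generation_sizes
    n_total = sum(sizes)
    starts = np.cumsum([0] + sizes[:-1])
    gen_slices = [
        np.arange(s, s + size) for s, size in zip(starts, sizes)
    ]

    # Founders: frequencies Uniform(0.05, 0.5); allele copies independent.
    founder_p = rng.uniform(0.05, 0.5, size=L)
    hap = np.zeros((n_total, L, 2), dtype=np.int8)
    origin = np.zeros((n_total, L, 2), dtype=np.int32)
    nF = sizes[0]
    hap[:nF] = (rng.random((nF, L, 2)) < founder_p[None, :, None]).astype(np.int8)
    origin[:nF] = (
        2 * np.arange(nF)[:, None, None] + np.array([0, 1])[None, None, :]
    )

    ids: list[str] = [f"G0_{k + 1}" for k in range(nF)]
    sires: list[str] = [UNKNOWN] * nF
    dams: list[str] = [UNKNOWN] * nF
    generation: list[int] = [0] * nF
    sex = np.empty(n_total, dtype=np.int8)
    sex[:nF] = np.arange(nF) % 2  # 0 = sire, 1 = dam, alternating

    for g in range(1, config.n_generations):
        parents = gen_slices[g - 1]
        males = rng.permutation(parents[sex[parents] == 0])
        females = rng.permutation(parents[sex[parents] == 1])
        n_pairs = min(len(males), len(females))
        males, females = males[:n_pairs], females[:n_pairs]
        offspring = gen_slices[g]
        k_off = config.offspring_per_mating
        sire_idx = np.repeat(males, k_off)
        dam_idx = np.repeat(females, k_off)
        for j, (si, di) in enumerate(zip(sire_idx, dam_idx)):
            ids.append(f"G{g}_{j + 1}")
            sires.append(ids[si])
            dams.append(ids[di])
            generation.append(g)
        pat = _gamete_strands(rng, len(offspring), switch_p)
        mat = _gamete_strands(rng, len(offspring), switch_p)
        hap[offspring, :, 0] = _pick(hap[sire_idx], pat)
        hap[offspring, :, 1] = _pick(hap[dam_idx], mat)
        origin[offspring, :, 0] = _pick(origin[sire_idx], pat)
        origin[offspring, :, 1] = _pick(origin[dam_idx], mat)
        sex[offspring] = np.arange(len(offspring)) % 2

    pedigree = Pedigree(tuple(ids), tuple(sires), tuple(dams))
    counts = hap.sum(axis=2).astype(float)
    genotypes = GenotypeMatrix(ids=list(ids), loci=loci, counts=counts)

    # QTL effects on trajectory coefficients.
    beta = np.zeros((n_total, 3))
    qtl_effects = pd.DataFrame(
        columns=["snp_id", "chromosome", "alpha0", "alpha1", "alpha2"]
    )
    if config.n_qtl > 0:
        q1, q2 = _qtl_indices(rng, config, chrom)
        if len(q2) == 0:
            f = 1.0
        elif len(q1) == 0:
            f = 0.0
        else:
            f = config.fraction_qtl_variance_on_chr1
        centred = counts - counts.mean(axis=0)
        alphas = np.zeros((config.n_qtl, 3))
        qtl_all = np.concatenate([q1, q2])
        for k, total_var in enumerate(COEF_VARIANCES):
            a1 = rng.standard_normal(len(q1))
            a2 = rng.standard_normal(len(q2))
            u1 = centred[:, q1] @ a1 if len(q1) else np.zeros(n_total)
            u2 = centred[:, q2] @ a2 if len(q2) else np.zeros(n_total)
            u1, c1 = _scaled(u1, f * total_var)
            u2, c2 = _scaled(u2, (1.0 - f) * total_var)
            b = u1 + u2
            b, c_all = _scaled(b, total_var)
            beta[:, k] = b
            alphas[: len(q1), k] = a1 * c1 * c_all
            alphas[len(q1):, k] = a2 * c2 * c_all
        qtl_effects = pd.DataFrame(
            {
                "snp_id": loci["snp_id"].to_numpy()[qtl_all],
                "chromosome": loci["chromosome"].to_numpy()[qtl_all],
                "alpha0": alphas[:, 0],
                "alpha1": alphas[:, 1],
                "alpha2": alphas[:, 2],
            }
        )

    all_times = np.asarray(config.all_times)
    bv = (
        beta[:, [0]]
        + beta[:, [1]] * all_times[None, :]
        + beta[:, [2]] * all_times[None, :] ** 2
    )
    true_bv = pd.DataFrame(bv, index=list(ids), columns=list(all_times))
    true_bv.index.name = "id"

    # Mask validation animals (final generation).
    final = gen_slices[-1]
    if config.n_validation_unphenotyped == len(final):
        masked = final
    else:
        masked = np.sort(
            rng.choice(final, size=config.n_validation_unphenotyped, replace=False)
        )
    masked_ids = [ids[i] for i in masked]
    masked_set = set(masked)
    pheno_idx = np.array([i for i in range(n_total) if i not in masked_set])

    # Phenotypes: residual variance tied to realised genetic variance so the
    # heritability stays near target at every time point.
    h2 = config.target_heritability
    records = []
    for t in config.time_points:
        bv_t = bv[:, list(all_times).index(t)]
        vg = float(np.var(bv_t[pheno_idx], ddof=1)) if len(pheno_idx) > 1 else 0.0
        ve = vg * (1.0 - h2) / h2 if vg > 0.0 else 1.0
        e = rng.normal(0.0, np.sqrt(ve), size=len(pheno_idx))
        vals = mean_curve(t) + bv_t[pheno_idx] + e
        for i, v in zip(pheno_idx, vals):
            records.append((ids[i], t, v))
    phenotypes = pd.DataFrame(records, columns=["id", "time", "value"])

    return TruePopulation(
        pedigree=pedigree,
        genotypes=genotypes,
        phenotypes=phenotypes,
        true_bv=true_bv,
        masked_ids=masked_ids,
        generation=pd.Series(generation, index=list(ids), name="generation"),
        config=config,
        qtl_effects=qtl_effects,
        founder_origin=origin,
        haplotypes=hap,
    )


# ------------------------------- persistence -------------------------------


def write_population(pop: TruePopulation, directory: str | Path) -> dict[str, Path]:
    """Write the population tables as plain text; round-trips losslessly.

    Files: ``pedigree.csv``, ``genotypes.txt`` + ``map.txt``,
    ``phenotypes.csv`` (masked animals absent), ``true_bv.csv`` (long) and
    ``validation_ids.txt``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": directory / "pedigree.csv",
        "genotypes": directory / "genotypes.txt",
        "map": directory / "map.txt",
        "phenotypes": directory / "phenotypes.csv",
        "true_bv": directory / "true_bv.csv",
        "validation_ids": directory / "validation_ids.txt",
    }
    pop.pedigree.to_csv(paths["pedigree"])
    pop.genotypes.write(paths["genotypes"], paths["map"])
    # %.17g round-trips float64 exactly, keeping the pipeline checkpointable
    pop.phenotypes.to_csv(paths["phenotypes"], index=False, float_format="%.17g")
    long_bv = pop.true_bv.reset_index().melt(
        id_vars="id", var_name="time", value_name="true_bv"
    )
    long_bv.to_csv(paths["true_bv"], index=False, float_format="%.17g")
    paths["validation_ids"].write_text("\n".join(pop.masked_ids) + "\n")
    return paths


def pedigree_generations(ped: Pedigree) -> pd.Series:
    """Generation number per individual (founders 0, else 1 + max parent)."""
    pos = ped.index
    gen = np.zeros(len(ped), dtype=int)
    from .pedigree import sort_pedigree

    for i in sort_pedigree(ped).ids:
        k = pos[i]
        s, d = ped.sires[k], ped.dams[k]
        parent_gen = [gen[pos[p]] for p in (s, d) if p != UNKNOWN]
        gen[k] = 1 + max(parent_gen) if parent_gen else 0
    return pd.Series(gen, index=list(ped.ids), name="generation")


def read_population(directory: str | Path) -> TruePopulation:
    """Read a population written by :func:`write_population`."""
    directory = Path(directory)
    pedigree = Pedigree.read_csv(directory / "pedigree.csv")
    genotypes = GenotypeMatrix.read(
        directory / "genotypes.txt", directory / "map.txt"
    )
    # round_trip parsing restores the exact float64 values written above
    phenotypes = pd.read_csv(
        directory / "phenotypes.csv", float_precision="round_trip"
    )
    phenotypes["id"] = phenotypes["id"].astype(str)
    phenotypes["time"] = phenotypes["time"].astype(float)
    long_bv = pd.read_csv(directory / "true_bv.csv", float_precision="round_trip")
    long_bv["id"] = long_bv["id"].astype(str)
    long_bv["time"] = long_bv["time"].astype(float)
    true_bv = long_bv.pivot(index="id", columns="time", values="true_bv")
    true_bv = true_bv.loc[list(pedigree.ids)]
    masked = [
        line.strip()
        for line in (directory / "validation_ids.txt").read_text().splitlines()
        if line.strip()
    ]
    return TruePopulation(
        pedigree=pedigree,
        genotypes=genotypes,
        phenotypes=phenotypes,
        true_bv=true_bv,
        masked_ids=masked,
        generation=pedigree_generations(pedigree),
    )
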