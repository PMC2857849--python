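# Methods

This note documents the models, estimators, numerical choices and known
limitations of `snpblup`, and what the synthetic data do and do not show
about real populations.

## Study design

The package implements a single-masked-generation validation design for a
longitudinal trait: all animals are pedigree-recorded and genotyped; earlier
generations carry phenotypes at five time points (0, 132, 265, 397, 530);
the final generation is masked and must be predicted at a sixth, unobserved
time (600). Three genetic covariance matrices compete: pedigree expectation
(PB), a marker moment estimator (SNPL), and an averaged local genomic
relationship (SNPC), the latter two restricted to chromosome 1 — the
chromosome carrying the dominant QTL variance — mirroring a workflow in
which software limits force a single-chromosome analysis.

## Relationship matrices

**PB.** The additive relationship matrix is built by the tabular method on a
topologically sorted pedigree; unknown parents contribute 0 and create no
phantom groups. The diagonal is 1 + F with F the inbreeding coefficient.
Henderson-style direct construction of A⁻¹ is deliberately omitted: at desk
scale (≲ a few thousand animals) the dense matrix is inverted numerically by
Cholesky where needed.

**SNPL.** For biallelic SNPs with counted-allele frequency `p_l` and
genotype counts `g`, the pairwise estimator reduces to

    a_ij = Σ_l [ (g_il − 2p_l)(g_jl − 2p_l)/2 + 2p_l(1−p_l)/(n_l−1) ]
           / Σ_l 2p_l(1−p_l)

where `n_l` is the number of defined allele copies at locus *l* (individuals
× ploidy − missing copies). The per-allele sum runs over both alleles, whose
terms are equal in the biallelic case. Frequencies and `n_l` always use the
full reference sample (all genotyped animals); loci with a missing call in
either member of a pair are excluded from that pair's numerator. The
estimator is defined pairwise, so diagonals are filled afterwards as
`a_kk = 1 + 0.5·m(sire_k, dam_k)` from the marker relationship of the
parents, defaulting to 1 when a parent is unknown or ungenotyped.

**SNPC.** Locus-specific IBD matrices from an MCMC multilocus sampler are
external to this package; `read_ibd_matrices` ingests them when available.
The built-in deterministic substitute computes, at each of `n_points`
(default 9) equally spaced map positions, a local VanRaden-type genomic
relationship on the `max(10, ceil(L/n_points))` map-nearest loci, and
averages the matrices elementwise. Input loci are first restricted to one
chromosome and filtered to minor allele frequency strictly above 0.1. The
substitute shares the averaging structure and locality of the MCMC approach
but not its probabilistic treatment of unobserved descent; results under
SNPC should be read as "local-GRM averaging", not as an IBD-sampler
replication.

**Bending.** Marker matrices are not guaranteed invertible. If the minimum
eigenvalue is below ε (default 1e−6), `epsilon − λ_min` is added to every
diagonal element; the applied shift is recorded in the matrix and the run
log. Matrices already positive definite pass through unchanged.

## Animal model

Each time point is fitted independently (no repeated-measures covariance),
with the intercept as the only fixed effect. REML depends on the data only
through the phenotyped submatrix `Gp` of `G`, so `fit_reml` works in the
eigenbasis of `Gp`: one symmetric eigendecomposition, then O(n) per
iteration. The update is the classical EM step — conditional expectations of
`a'Gp⁻¹a` and `e'e` given the data — which keeps both components nonnegative
by construction and makes the restricted log-likelihood non-decreasing every
iteration; the test suite asserts this trace property. Starting values are
`σ²_a = σ²_e = var(y)/2`; convergence is a relative parameter change below
1e−6; the iteration cap is 500, with non-convergence flagged and the last
iterate returned (EM's terminal convergence is slow when the likelihood is
flat, e.g. at very high estimated h²; flagged fits are still usable
maximizer approximations). An additive variance collapsing below 1e−6 of the
phenotypic variance sets a boundary flag.

Breeding values solve Henderson's mixed model equations over all animals,
with `G⁻¹` obtained by Cholesky (reused across time points within a run).
The solution is checked against the right-hand side to a relative residual
of 1e−8; failure raises an error carrying the condition number. The
closed-form GLS conditional-expectation solution serves as an independent
oracle in the tests, never as the production path.

An identifiability note: with `G = I` and one record per animal, σ²_a and
σ²_e enter the likelihood only through their sum, so null-signal recovery
tests use a family-structured pedigree covariance instead.

## Trajectory extrapolation

Per-animal ordinary least squares of EBV on (1, t, t²) over the five fitted
time points, evaluated at t = 600. Time is internally centred and scaled,
t′ = (t − mean)/halfrange, because raw t² reaches 2.8×10⁵ and conditions the
design poorly; coefficients are mapped back to the raw basis for reporting.
The quadratic deliberately ignores that a growth trait eventually
asymptotes; that bias is part of the workflow being studied, not something
the package corrects. Because the generator makes true breeding values
exactly quadratic in time, extrapolating *true* values reproduces the
held-out time to machine precision — so all prediction error measured
downstream is attributable to EBV estimation, not to trajectory-model
misspecification.

## Synthetic populations

The generator's defaults define the study conditions: 40 founders, two
descendant generations with 10 offspring per mating (1240 animals; the final
1000 are masked as validation), 5 chromosomes × 100 equally spaced SNPs on a
1-Morgan map, founder allele frequencies Uniform(0.05, 0.5), gene dropping
with Haldane (no-interference) recombination and founder-origin labels
carried along for verification. Thirty panel loci act as QTLs; their allelic
effects load on the animal's trajectory coefficients (β0, β1, β2), scaled so
the realised coefficient variances are 0.05, 2.5×10⁻⁵ and 1.5×10⁻¹⁰ — giving
genetic variance growing from ≈0.05 at t=0 to ≈19 at t=530, the magnitude
pattern of a growth-like trait — with 70% of each coefficient's variance
from chromosome-1 QTLs. Residual variance per time point is tied to the
realised genetic variance so heritability stays ≈0.5 throughout. Phenotypes
add a fixed quadratic mean curve. All draws come from one seeded generator;
identical configurations produce byte-identical files. Population structure,
marker density and QTL counts are package assumptions chosen as realistic
for a moderately sized experimental mapping population, not facts about any
particular dataset.

What the synthetic data deliberately do not contain: hidden QTLs in
linkage disequilibrium with (rather than inside) the panel, multi-allelic
markers, genotyping error, missing genotypes, selection or non-random
mating, epistasis, and genotype-by-time interactions beyond the quadratic.
Passing tests therefore demonstrate correctness of the estimators and the
qualitative mechanism (marker matrices capture Mendelian sampling that
pedigree expectation cannot), not quantitative accuracy levels transferable
to real livestock data — where QTLs are unobserved and the marker advantage
is typically smaller.

## Problem sizes used in the automated checks

Multi-seed suites (heritability recovery, method ordering) run on reduced
populations — 260 animals with 180 validation for pipeline-level checks,
n = 1000 for single-model REML recovery — sizes chosen so that ten-seed
Monte Carlo means are stable while the whole suite stays fast. The
acceptance script runs the full default 1240-animal population.

## Evaluation conventions

All truth-based metrics are computed over the validation (non-phenotyped)
animals only. Correlations are Pearson throughout; the regression of true on
predicted is cov/var of predictions (slope < 1 ⇒ inflated prediction
spread). Top-N overlap breaks ties by descending value then ascending id.
Within-family spread is the SD (ddof = 1) of predictions among full sibs
(shared sire and dam); singleton families are flagged and reported with SD
0. Expect, and the tests assert, within-family SD exactly 0 under PB for
unphenotyped sib families without phenotyped descendants, positive under
marker matrices.

## Known limitations

* EM-REML converges slowly near likelihood ridges; an average-information
  accelerator is a natural extension but is not implemented.
* The SNPC substitute is not an IBD-probability model; treat its absolute
  variance-component estimates with caution.
* No reliabilities/standard errors of EBVs are produced, and no multi-trait
  or random-regression machinery — per-time-point fits plus post-hoc
  quadratic regression only, by design.
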