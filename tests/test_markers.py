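import numpy as np
import pandas as pd
import pytest

import snpblup as sb

from .oracles import loiselle_naive
from .test_genotypes import make_panel


class TestLoiselleWorkedExamples:
    """Hand-evaluated values for a 10-diploid reference sample (n_l = 20)."""

    def test_both_heterozygous_single_locus(self):
        # one locus, everyone heterozygous: p = 0.5, cross-term 0,
        # a_ij = (2 * 0.25 / 19) / (2 * 0.25) = 1/19
        G = make_panel(np.ones((10, 1)))
        M = sb.loiselle_relatedness(G)
        assert M.loc("i0", "i1") == pytest.approx(1 / 19, abs=1e-12)

    def test_both_homozygous_counted_allele(self):
        # 5 animals with 2 copies, 5 with 0: p = 0.5
        counts = np.repeat([2.0, 0.0], 5)[:, None]
        M = sb.loiselle_relatedness(make_panel(counts))
        assert M.loc("i0", "i1") == pytest.approx((0.5 + 0.5 / 19) / 0.5, abs=1e-12)
        assert M.loc("i0", "i1") == pytest.approx(1.0526, abs=1e-4)

    def test_locus_permutation_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 3, size=(8, 6)).astype(float)
        M1 = sb.loiselle_relatedness(make_panel(counts))
        perm = rng.permutation(6)
        M2 = sb.loiselle_relatedness(make_panel(counts[:, perm]))
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_allclose(M1.values[off], M2.values[off], atol=1e-12)

    def test_all_monomorphic_rejected(self):
        with pytest.raises(sb.NumericalError, match="monomorphic"):
            sb.loiselle_relatedness(make_panel(np.zeros((5, 3))))


class TestLoiselleOracle:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quadruple_loop(self, seed):
        """Vectorised estimator equals the literal per-allele, per-copy sum."""
        rng = np.random.default_rng(seed)
        n, L = rng.integers(3, 6), rng.integers(2, 5)
        counts = rng.integers(0, 3, size=(n, L)).astype(float)
        if np.all(counts == counts[0:1, :]):  # avoid all-monomorphic panels
            counts[0, 0] = (counts[0, 0] + 1) % 3
        M = sb.loiselle_relatedness(make_panel(counts))
        expected = loiselle_naive(counts)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(M.values[off], expected[off], atol=1e-12)

    def test_diagonal_left_blank(self):
        M = sb.loiselle_relatedness(make_panel(np.ones((4, 2))))
        assert np.isnan(np.diag(M.values)).all()


class TestLoiselleStatistics:
    def test_unrelated_mean_near_zero_under_hwe(self):
        """Mean off-diagonal estimate over unrelated samples is ~0."""
        rng = np.random.default_rng(42)
        means = []
        for _ in range(50):
            p = rng.uniform(0.1, 0.5, size=30)
            counts = rng.binomial(2, p, size=(12, 30)).astype(float)
            if (counts.std(axis=0) == 0).all():
                continue
            M = sb.loiselle_relatedness(make_panel(counts))
            off = ~np.eye(12, dtype=bool)
            means.append(M.values[off].mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 3 * se + 1e-3

    def test_duplicate_has_highest_relationship_to_its_copy(self):
        rng = np.random.default_rng(7)
        counts = rng.binomial(2, rng.uniform(0.2, 0.5, 25), size=(10, 25)).astype(float)
        counts[9] = counts[0]  # i9 duplicates i0
        M = sb.loiselle_relatedness(make_panel(counts))
        row = M.values[0].copy()
        row[0] = -np.inf
        assert np.nanargmax(row) == 9

    def test_full_sibs_exceed_unrelated(self, small_population):
        """Mean Loiselle relatedness separates sib pairs from non-sib pairs."""
        pop = small_population
        g1 = sb.subset_chromosome(pop.genotypes, "1")
        M = sb.loiselle_relatedness(g1)
        fams = [m for m in pop.pedigree.full_sib_families().values() if len(m) >= 2]
        sib_vals, unrel_vals = [], []
        founders = [
            i for i, s in zip(pop.pedigree.ids, pop.pedigree.sires) if s == "0"
        ]
        for mem in fams[:10]:
            sib_vals.append(M.loc(mem[0], mem[1]))
        for a, b in zip(founders[:-1], founders[1:]):
            unrel_vals.append(M.loc(a, b))
        assert np.mean(sib_vals) > np.mean(unrel_vals)


class TestFillDiagonal:
    def test_founder_defaults_to_one_and_parents_fill(self, tiny_pedigree):
        # marker matrix over S, D, K, M with known off-diagonals
        labels = ["S", "D", "K", "M"]
        vals = np.full((4, 4), 0.1)
        vals[0, 1] = vals[1, 0] = 0.2  # m(S, D)
        vals[0, 2] = vals[2, 0] = 0.6  # m(S, K)
        np.fill_diagonal(vals, np.nan)
        M = sb.RelationshipMatrix(labels=labels, values=vals)
        filled = sb.fill_diagonal(M, tiny_pedigree)
        assert filled.loc("S", "S") == 1.0  # unknown parents
        assert filled.loc("K", "K") == pytest.approx(1.0 + 0.5 * 0.2)
        assert filled.loc("M", "M") == pytest.approx(1.0 + 0.5 * 0.6)
        assert not np.isnan(filled.values).any()
        np.testing.assert_allclose(filled.values, filled.values.T)

    def test_id_missing_from_pedigree_raises(self, tiny_pedigree):
        M = sb.RelationshipMatrix(labels=["X", "Y"], values=np.eye(2))
        with pytest.raises(sb.DataError, match="missing from pedigree"):
            sb.fill_diagonal(M, tiny_pedigree)


class TestLocalRelationshipAverage:
    def test_single_point_full_window_equals_global_grm(self):
        rng = np.random.default_rng(1)
        counts = rng.binomial(2, 0.4, size=(8, 12)).astype(float)
        G = make_panel(counts)
        single = sb.local_relationship_average(G, n_points=1, window_loci=12)
        p = sb.allele_frequencies(G).p
        dev = counts - 2 * p
        expected = dev @ dev.T / (2 * p * (1 - p)).sum()
        np.testing.assert_allclose(single.values, expected, atol=1e-12)

    def test_mean_of_identical_windows_is_that_matrix(self):
        rng = np.random.default_rng(2)
        counts = rng.binomial(2, 0.4, size=(6, 10)).astype(float)
        G = make_panel(counts)
        one = sb.local_relationship_average(G, n_points=1, window_loci=10)
        many = sb.local_relationship_average(G, n_points=5, window_loci=10)
        np.testing.assert_allclose(many.values, one.values, atol=1e-12)

    def test_invalid_n_points(self):
        G = make_panel(np.ones((4, 3)))
        with pytest.raises(sb.ConfigError):
            sb.local_relationship_average(G, n_points=0)

    def test_too_few_loci(self):
        G = make_panel(np.ones((4, 3)))
        with pytest.raises(sb.DataError, match="need >= 9"):
            sb.local_relationship_average(G, n_points=9)


class TestAverageAndReadMatrices:
    def test_elementwise_mean(self):
        m1 = sb.RelationshipMatrix(["a", "b"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        m2 = sb.RelationshipMatrix(["a", "b"], np.array([[1.0, 0.4], [0.4, 1.0]]))
        avg = sb.average_matrices([m1, m2])
        assert avg.loc("a", "b") == pytest.approx(0.3)

    def test_read_nine_conformable(self, tmp_path):
        rng = np.random.default_rng(0)
        paths = []
        for k in range(9):
            X = rng.standard_normal((3, 3))
            m = sb.RelationshipMatrix(["a", "b", "c"], X @ X.T)
            p = tmp_path / f"ibd{k}.txt"
            m.write(p)
            paths.append(p)
        mats = sb.read_ibd_matrices(paths)
        assert len(mats) == 9
        avg = sb.average_matrices(mats)
        assert avg.n == 3

    def test_mismatched_labels_rejected(self, tmp_path):
        sb.RelationshipMatrix(["a", "b"], np.eye(2)).write(tmp_path / "m1.txt")
        sb.RelationshipMatrix(["a", "c"], np.eye(2)).write(tmp_path / "m2.txt")
        with pytest.raises(sb.FormatError, match="labels differ"):
            sb.read_ibd_matrices([tmp_path / "m1.txt", tmp_path / "m2.txt"])

    def test_empty_list_rejected(self):
        with pytest.raises(sb.ConfigError):
            sb.read_ibd_matrices([])


class TestBendToPD:
    def test_pd_matrix_unchanged(self):
        M = sb.RelationshipMatrix(["a", "b"], np.array([[1.0, 0.2], [0.2, 1.0]]))
        bent = sb.bend_to_pd(M, epsilon=1e-6)
        np.testing.assert_array_equal(bent.values, M.values)
        assert bent.bend_shift == 0.0

    def test_rank_one_matrix_shifted_by_epsilon(self):
        # eigenvalues {0, 2}: the required shift is exactly epsilon
        M = sb.RelationshipMatrix(["a", "b"], np.ones((2, 2)))
        bent = sb.bend_to_pd(M, epsilon=1e-6)
        assert bent.bend_shift == pytest.approx(1e-6)
        assert bent.min_eigenvalue() >= 1e-6 - 1e-15

    def test_shift_is_nonnegative_multiple_of_identity(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((5, 2))
        M = sb.RelationshipMatrix([f"i{k}" for k in range(5)], X @ X.T)
        bent = sb.bend_to_pd(M, epsilon=1e-6)
        diff = bent.values - M.values
        shift = diff[0, 0]
        assert shift >= 0
        np.testing.assert_allclose(diff, shift * np.eye(5), atol=1e-15)

    def test_asymmetric_input_rejected_at_construction(self):
        with pytest.raises(sb.FormatError, match="symmetric"):
            sb.RelationshipMatrix(["a", "b"], np.array([[1.0, 0.3], [0.2, 1.0]]))
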