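import numpy as np
import pandas as pd
import pytest

import snpblup as sb

from .conftest import random_pedigree
from .oracles import gls_blup


def pedigree_A(n: int, seed: int = 0) -> sb.RelationshipMatrix:
    ped = random_pedigree(np.random.default_rng(seed), n)
    return sb.additive_relationship(ped)


def simulate_y(
    A: sb.RelationshipMatrix, sa: float, se: float, seed: int, mu: float = 10.0
) -> pd.Series:
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(A.values + 1e-10 * np.eye(A.n))
    a = np.sqrt(sa) * (L @ rng.standard_normal(A.n))
    return pd.Series(mu + a + rng.normal(0, np.sqrt(se), A.n), index=A.labels)


class TestFitReml:
    def test_pure_noise_gives_low_heritability(self):
        """With no genetic signal in the data, the additive component
        collapses toward zero.  (The covariance structure must differ from
        the identity: with G = I and one record per animal the two components
        are confounded, so a family-structured A is used.)"""
        A = pedigree_A(500, seed=8)
        h2s = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = pd.Series(rng.normal(0, 1, A.n), index=A.labels)
            h2s.append(sb.fit_reml(y, A).h2)
        assert np.mean(h2s) <= 0.1

    def test_recovers_moderate_heritability(self):
        A = pedigree_A(400, seed=1)
        h2s = []
        for seed in range(10):
            y = simulate_y(A, 2.0, 2.0, seed)
            h2s.append(sb.fit_reml(y, A).h2)
        assert abs(np.mean(h2s) - 0.5) < 0.05

    def test_loglik_nondecreasing_every_iteration(self):
        A = pedigree_A(150, seed=2)
        y = simulate_y(A, 1.0, 3.0, seed=5)
        vc = sb.fit_reml(y, A)
        assert (np.diff(vc.loglik_trace) > -1e-8).all()

    def test_deterministic(self):
        A = pedigree_A(60, seed=3)
        y = simulate_y(A, 1.0, 1.0, seed=0)
        v1, v2 = sb.fit_reml(y, A), sb.fit_reml(y, A)
        assert v1.sigma2_a == v2.sigma2_a
        assert v1.sigma2_e == v2.sigma2_e

    def test_too_few_records_rejected(self):
        G = sb.RelationshipMatrix(["a", "b", "c"], np.eye(3))
        y = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(sb.DataError, match=">= 10"):
            sb.fit_reml(y, G)

    def test_indefinite_submatrix_rejected(self):
        n = 12
        vals = np.ones((n, n)) - 2 * np.eye(n)  # eigenvalue n-2 and -2
        G = sb.RelationshipMatrix([f"i{k}" for k in range(n)], vals)
        y = pd.Series(np.arange(n, dtype=float), index=G.labels)
        with pytest.raises(sb.NumericalError, match="bend"):
            sb.fit_reml(y, G)


class TestHeritability:
    @pytest.mark.parametrize(
        "sa,se,expected",
        [(19.23, 21.32, 0.47), (6.50, 9.58, 0.40), (0.0, 1.0, 0.0)],
    )
    def test_worked_examples_two_decimals(self, sa, se, expected):
        assert round(sb.heritability(sa, se), 2) == expected

    def test_undefined_for_zero_total(self):
        with pytest.raises(sb.NumericalError):
            sb.heritability(0.0, 0.0)


class TestSolveBlup:
    def make_case(self, q=80, n=50, seed=4):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((q, q + 5))
        G = sb.RelationshipMatrix(
            [f"i{k}" for k in range(q)], X @ X.T / (q + 5) + 0.3 * np.eye(q)
        )
        pheno_idx = np.sort(rng.choice(q, n, replace=False))
        y = pd.Series(
            rng.normal(5, 2, n), index=[G.labels[i] for i in pheno_idx]
        )
        vc = sb.VarianceComponents(1.2, 0.8, 0.0, 1, True)
        return G, pheno_idx, y, vc

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_gls_oracle(self, seed):
        G, idx, y, vc = self.make_case(seed=seed)
        sol = sb.solve_blup(y, G, vc)
        mu, a = gls_blup(G.values, idx, y.to_numpy(), vc.sigma2_a, vc.sigma2_e)
        assert sol.mu == pytest.approx(mu, abs=1e-6)
        np.testing.assert_allclose(sol.ebv.to_numpy(), a, atol=1e-6)

    def test_shift_invariance(self):
        G, idx, y, vc = self.make_case()
        s1 = sb.solve_blup(y, G, vc)
        s2 = sb.solve_blup(y + 7.5, G, vc)
        assert s2.mu - s1.mu == pytest.approx(7.5, abs=1e-8)
        np.testing.assert_allclose(
            s1.ebv.to_numpy(), s2.ebv.to_numpy(), atol=1e-8
        )

    def test_vanishing_additive_variance_shrinks_to_zero(self):
        G, idx, y, _ = self.make_case()
        vc = sb.VarianceComponents(1e-10, 1.0, 0.0, 1, True)
        sol = sb.solve_blup(y, G, vc)
        assert np.abs(sol.ebv.to_numpy()).max() < 1e-4

    def test_method_tag_does_not_change_solution(self, tiny_pedigree):
        """The solver is agnostic to whether G came from pedigree or markers."""
        A = sb.additive_relationship(tiny_pedigree)
        marker_view = sb.RelationshipMatrix(
            list(A.labels), A.values.copy(), method="SNPL"
        )
        y = pd.Series([1.0, 2.0, 1.5], index=["S", "D", "K"])
        vc = sb.VarianceComponents(1.0, 1.0, 0.0, 1, True)
        s1 = sb.solve_blup(y, A, vc)
        s2 = sb.solve_blup(y, marker_view, vc)
        np.testing.assert_allclose(s1.ebv.to_numpy(), s2.ebv.to_numpy())

    def test_unphenotyped_identical_twin_gets_equal_ebv(self):
        rng = np.random.default_rng(11)
        q = 30
        X = rng.standard_normal((q, q))
        vals = X @ X.T / q + 0.3 * np.eye(q)
        big = np.empty((q + 1, q + 1))  # append a twin of animal 0
        big[:q, :q] = vals
        big[q, :q] = vals[0]
        big[:q, q] = vals[:, 0]
        big[q, q] = vals[0, 0]
        vals = big
        labels = [f"i{k}" for k in range(q)] + ["twin"]
        G = sb.bend_to_pd(
            sb.RelationshipMatrix(labels, 0.5 * (vals + vals.T)), 1e-6
        )
        y = pd.Series(rng.normal(0, 1, q - 5), index=labels[: q - 5])
        vc = sb.VarianceComponents(1.0, 1.0, 0.0, 1, True)
        sol = sb.solve_blup(y, G, vc)
        assert sol.ebv["twin"] == pytest.approx(sol.ebv["i0"], abs=1e-4)


class TestFullSibProperty:
    def test_pedigree_equalizes_sibs_markers_separate_them(self, small_population):
        """Unphenotyped full sibs share one parent-average EBV under the
        pedigree matrix; their distinct genotypes separate them under the
        marker matrix."""
        pop = small_population
        cfg = sb.RunConfig(simulation=pop.config, output_dir="unused")
        log: list[str] = []
        A = sb.build_relationship_matrix("PB", pop, cfg, log)
        M = sb.build_relationship_matrix("SNPL", pop, cfg, log)
        t = pop.config.time_points[-1]
        y = (
            pop.phenotypes.query("time == @t")
            .set_index("id")["value"]
            .astype(float)
        )
        fam = next(
            m
            for m in pop.pedigree.full_sib_families().values()
            if set(m) <= set(pop.masked_ids)
        )
        for G, spread_expected in ((A, False), (M, True)):
            vc = sb.fit_reml(y, G)
            sol = sb.solve_blup(y, G, vc)
            sd = float(sol.ebv[fam].std(ddof=1))
            if spread_expected:
                assert sd > 1e-4
            else:
                assert sd < 1e-8


class TestRunAnimalModel:
    def test_per_time_point_fits(self, small_population):
        pop = small_population
        A = sb.additive_relationship(pop.pedigree)
        vc, ebv = sb.run_animal_model(pop.phenotypes, A)
        assert list(vc["time"]) == list(pop.config.time_points)
        assert ebv.shape == (len(pop.pedigree), 5)
        assert set(ebv.index) == set(pop.pedigree.ids)

    def test_duplicate_records_rejected(self, small_population):
        pop = small_population
        A = sb.additive_relationship(pop.pedigree)
        dup = pd.concat([pop.phenotypes, pop.phenotypes.iloc[[0]]])
        with pytest.raises(sb.DataError, match="one phenotype record"):
            sb.run_animal_model(dup, A)
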