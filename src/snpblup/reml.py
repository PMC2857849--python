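"""Single-trait animal model: EM-REML variance components and BLUP.

Model per time point, for phenotyped animals i:

    y_i = mu + a_i + e_i,    var(a) = G sigma2_a,    var(e) = I sigma2_e,

with ``G`` any (pedigree- or marker-based) relationship matrix over all
animals and an intercept as the only fixed effect.

REML depends on the data only through the phenotyped submatrix ``Gp`` of
``G``, so the fit works in the eigenbasis of ``Gp``: one symmetric
eigendecomposition, then O(n) work per EM iteration.  The EM update is the
classical conditional-expectation step (of ``a' Gp^{-1} a`` and ``e'e``),
which makes the restricted log-likelihood non-decreasing across iterations —
a property the test suite asserts per iteration.  Variance components stay
nonnegative by construction of the EM step; a vanishing additive variance is
reported via the ``boundary`` flag.

Breeding values for *all* animals (phenotyped or not) come from Henderson's
mixed model equations with shrinkage ``lambda = sigma2_e / sigma2_a``:

    [ X'X   X'Z           ] [mu_hat]   [X'y]
    [ Z'X   Z'Z + G^-1 λ  ] [a_hat ] = [Z'y]

Non-phenotyped animals receive predictions through the off-diagonals of G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import DataError, NumericalError
from .relmat import RelationshipMatrix


@dataclass
class VarianceComponents:
    """REML estimates for one time point."""

    sigma2_a: float
    sigma2_e: float
    loglik: float
    n_iter: int
    converged: bool
    boundary: bool = False
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def h2(self) -> float:
        return heritability(self.sigma2_a, self.sigma2_e)


def heritability(sigma2_a: float, sigma2_e: float) -> float:
    """h2 = sigma2_a / (sigma2_a + sigma2_e)."""
    total = sigma2_a + sigma2_e
    if total <= 0.0:
        raise NumericalError("heritability undefined: zero total variance")
    return sigma2_a / total


def _restricted_loglik(
    sa: float, se: float, d: np.ndarray, t: np.ndarray, s: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Restricted log-likelihood (up to an additive constant) in eigenbasis.

    Returns (loglik, mu_hat, w) where ``w`` are the eigen-coordinates of Py.
    """
    v = sa * d + se
    sWs = float(np.sum(s * s / v))
    mu = float(np.sum(s * t / v) / sWs)
    w = (t - s * mu) / v
    yPy = float(np.sum(t * w))
    ll = -0.5 * (float(np.sum(np.log(v))) + np.log(sWs) + yPy)
    return ll, mu, w


def fit_reml(
    y: pd.Series,
    G: RelationshipMatrix,
    tolerance: float = 1e-6,
    max_iter: int = 500,
) -> VarianceComponents:
    """EM-REML for the intercept-only animal model.

    Parameters
    ----------
    y
        Phenotypes indexed by individual id (each id present in ``G``).
    G
        Relationship matrix over all animals; its phenotyped submatrix must be
        positive definite (bend first if necessary).
    tolerance
        Relative-change convergence threshold on both components.
    max_iter
        Iteration cap; non-convergence is flagged, last iterate returned.
    """
    if y.index.has_duplicates:
        raise DataError("duplicate phenotype records for an individual")
    n = len(y)
    if n < 10:
        raise DataError(f"need >= 10 phenotyped individuals, got {n}")
    Gp = G.submatrix(list(y.index.astype(str)))
    d, U = np.linalg.eigh(Gp)
    if d.min() < -1e-8:
        raise NumericalError(
            f"phenotyped submatrix of G is not positive semi-definite "
            f"(min eigenvalue {d.min():.3g}); bend the matrix first"
        )
    d = np.clip(d, 0.0, None)
    yv = y.to_numpy(dtype=float)
    vary = float(np.var(yv, ddof=1))
    if vary <= 0.0:
        raise DataError("phenotype variance is zero")
    t = U.T @ yv
    s = U.T @ np.ones(n)

    floor = 1e-12 * vary
    sa = se = vary / 2.0
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, _, w = _restricted_loglik(sa, se, d, t, s)
        trace.append(ll)
        v = sa * d + se
        sWs = float(np.sum(s * s / v))
        trP = float(np.sum(1.0 / v)) - float(np.sum(s * s / v**2)) / sWs
        trPG = float(np.sum(d / v)) - float(np.sum(s * s * d / v**2)) / sWs
        sa_new = sa + (sa * sa / n) * (float(np.sum(d * w * w)) - trPG)
        se_new = se + (se * se / n) * (float(np.sum(w * w)) - trP)
        sa_new = max(sa_new, floor)
        se_new = max(se_new, floor)
        rel = max(
            abs(sa_new - sa) / max(sa, floor), abs(se_new - se) / max(se, floor)
        )
        sa, se = sa_new, se_new
        if rel < tolerance:
            converged = True
            break
    ll, _, _ = _restricted_loglik(sa, se, d, t, s)
    trace.append(ll)
    return VarianceComponents(
        sigma2_a=sa,
        sigma2_e=se,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        boundary=sa < 1e-6 * vary,
        loglik_trace=np.asarray(trace),
    )


@dataclass
class BlupSolution:
    """Mixed-model-equation solution for one time point."""

    mu: float
    ebv: pd.Series  # indexed by all individuals in G
    residual_rel: float  # relative MME residual norm


def solve_blup(
    y: pd.Series,
    G: RelationshipMatrix,
    vc: VarianceComponents,
    G_inv: np.ndarray | None = None,
) -> BlupSolution:
    """Solve Henderson's mixed model equations for all animals in ``G``.

    ``G_inv`` may be supplied to reuse a precomputed inverse across time
    points; otherwise ``G`` is inverted via Cholesky.
    """
    if y.index.has_duplicates:
        raise DataError("duplicate phenotype records for an individual")
    q = G.n
    idx = G.indices(list(y.index.astype(str)))
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    lam = vc.sigma2_e / max(vc.sigma2_a, 1e-12 * (vc.sigma2_a + vc.sigma2_e))
    if G_inv is None:
        try:
            cf = scipy.linalg.cho_factor(G.values)
        except np.linalg.LinAlgError as e:
            raise NumericalError(f"G is not positive definite: {e}")
        G_inv = scipy.linalg.cho_solve(cf, np.eye(q))

    C = np.zeros((q + 1, q + 1))
    C[0, 0] = n
    z = np.zeros(q)
    z[idx] = 1.0
    C[0, 1:] = z
    C[1:, 0] = z
    C[1:, 1:] = np.diag(z) + lam * G_inv
    rhs = np.zeros(q + 1)
    rhs[0] = yv.sum()
    np.add.at(rhs, 1 + idx, yv)
    try:
        sol = scipy.linalg.solve(C, rhs, assume_a="sym")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as e:
        raise NumericalError(f"singular mixed-model equations: {e}")
    rhs_norm = float(np.linalg.norm(rhs))
    resid = float(np.linalg.norm(C @ sol - rhs)) / max(rhs_norm, 1e-300)
    if resid > 1e-8:
        raise NumericalError(
            f"MME solution inaccurate: relative residual {resid:.3g}, "
            f"condition number {np.linalg.cond(C):.3g}"
        )
    return BlupSolution(
        mu=float(sol[0]),
        ebv=pd.Series(sol[1:], index=list(G.labels), name="ebv"),
        residual_rel=resid,
    )


def run_animal_model(
    phenotypes: pd.DataFrame,
    G: RelationshipMatrix,
    tolerance: float = 1e-6,
    max_iter: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit each time point independently and collect EBVs for all animals.

    Parameters
    ----------
    phenotypes
        Long-format table with columns ``id``, ``time``, ``value``; at most
        one record per (id, time); every phenotyped id present in ``G``.

    Returns
    -------
    varcomp
        One row per time point: time, sigma2_a, sigma2_e, h2, loglik, n_iter,
        converged, mu.
    ebv
        Wide table, index = all individuals in ``G``, one column per time
        point.
    """
    need = {"id", "time", "value"}
    if not need <= set(phenotypes.columns):
        raise DataError(f"phenotype table lacks columns {sorted(need)}")
    if phenotypes.duplicated(subset=["id", "time"]).any():
        raise DataError("more than one phenotype record per (id, time)")
    cf = scipy.linalg.cho_factor(G.values)
    G_inv = scipy.linalg.cho_solve(cf, np.eye(G.n))
    rows = []
    ebv_cols = {}
    for time, grp in phenotypes.groupby("time", sort=True):
        yt = pd.Series(
            grp["value"].to_numpy(dtype=float), index=grp["id"].astype(str)
        )
        vc = fit_reml(yt, G, tolerance=tolerance, max_iter=max_iter)
        blup = solve_blup(yt, G, vc, G_inv=G_inv)
        rows.append(
            {
                "time": time,
                "sigma2_a": vc.sigma2_a,
                "sigma2_e": vc.sigma2_e,
                "h2": vc.h2,
                "loglik": vc.loglik,
                "n_iter": vc.n_iter,
                "converged": vc.converged,
                "mu": blup.mu,
            }
        )
        ebv_cols[time] = blup.ebv
    varcomp = pd.DataFrame(rows)
    ebv = pd.DataFrame(ebv_cols)
    ebv.index.name = "id"
    return varcomp, ebv
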