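"""Genetic correlations between metabolites via cross-trait LD-score regression.

For two traits with z-scores z1, z2 on a shared panel of M variants,

    E[z1_j * z2_j] = sqrt(n1 * n2) * rho_g * l_j / M + intercept,

so the weighted-regression slope of ``z1 z2`` on the LD score ``l`` times
``M / sqrt(n1 n2)`` estimates the genetic covariance ``rho_g``.  Standard
errors come from a delete-one block jackknife over LD blocks.  The matrix
pipeline follows estimate -> zero non-significant entries (P > 0.05) ->
weighted bending to positive semidefiniteness -> normalization to a
correlation matrix; bending weights are inversely proportional to the
variances of the covariance estimates, so precise entries move least and the
diagonal is held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import SNPPanel
from .sumstats import SummaryStats

__all__ = ["GeneticCovarianceMatrix", "CorrelationContext", "cross_trait_ldsc",
           "estimate_genetic_covariance_matrix", "sparsify",
           "weighted_bending", "cov_to_corr"]

_MIN_SHARED = 200


@dataclass
class GeneticCovarianceMatrix:
    cov: np.ndarray
    var_of_est: np.ndarray
    p: np.ndarray
    labels: list[str]
    zeroed: np.ndarray | None = None
    bent: bool = False
    mean_abs_change: float = 0.0

    def __post_init__(self) -> None:
        C = np.asarray(self.cov, dtype=float)
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("covariance matrix must be symmetric")
        self.cov = 0.5 * (C + C.T)
        if self.zeroed is None:
            self.zeroed = np.zeros_like(self.cov, dtype=bool)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.cov).min())


@dataclass
class CorrelationContext:
    """Metabolite correlation matrix Sigma entering the adjusted statistics."""

    sigma: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        S = np.asarray(self.sigma, dtype=float)
        if not np.allclose(S, S.T, atol=1e-8):
            raise ValueError("Sigma must be symmetric")
        if not np.allclose(np.diag(S), 1.0, atol=1e-8):
            raise ValueError("Sigma must have unit diagonal")
        self.min_eigenvalue = float(np.linalg.eigvalsh(S).min())
        if self.min_eigenvalue < -1e-8:
            raise ValueError("Sigma must be positive semidefinite")
        self.sigma = 0.5 * (S + S.T)

    @classmethod
    def from_estimate(cls, sigma: np.ndarray, labels: list[str] | None = None,
                      tol: float = 1e-6) -> "CorrelationContext":
        """Build a context from an estimated/round-tripped matrix.

        Rounding (file round-trips, submatrix extraction) can leave
        eigenvalues a hair below zero; negative eigenvalues within ``tol``
        are floored at zero and the diagonal renormalized.  Larger
        violations still raise.
        """
        S = 0.5 * (np.asarray(sigma, float) + np.asarray(sigma, float).T)
        lam, V = np.linalg.eigh(S)
        if lam.min() < -tol:
            raise ValueError(f"matrix is indefinite (min eigenvalue {lam.min():.3e})")
        if lam.min() < 0:
            S = (V * np.maximum(lam, 0.0)) @ V.T
            d = np.sqrt(np.diag(S))
            S = S / np.outer(d, d)
            np.fill_diagonal(S, 1.0)
        return cls(sigma=S, labels=labels or [])


def _ldsc_suffstats(y: np.ndarray, ell: np.ndarray, w: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant contributions to X'WX (flattened 2x2) and X'Wy."""
    A = np.stack([w, w * ell, w * ell, w * ell ** 2])       # (4, n)
    b = np.stack([w * y, w * ell * y])                      # (2, n)
    return A, b


def _slope_from_suffstats(A: np.ndarray, b: np.ndarray) -> float:
    beta = np.linalg.solve(A.reshape(2, 2), b)
    return float(beta[1])


def _ldsc_slope(y: np.ndarray, ell: np.ndarray, w: np.ndarray) -> float:
    A, b = _ldsc_suffstats(y, ell, w)
    return _slope_from_suffstats(A.sum(axis=1), b.sum(axis=1))


def cross_trait_ldsc(stats1: SummaryStats, stats2: SummaryStats,
                     panel: SNPPanel) -> tuple[float, float, float]:
    """Genetic covariance between two traits by cross-trait LDSC.

    Returns ``(cov_g, var_of_est, p)``.  With ``stats2 is stats1`` the slope
    estimates the trait's own SNP heritability.  Requires >= 200 shared
    variants and LD-score variation across the panel; the intercept is free,
    absorbing the null expectation (and any sample overlap).
    """
    if stats1.n_variants != panel.n_snps or stats2.n_variants != panel.n_snps:
        raise ValueError("summary statistics must match the panel")
    if panel.n_snps < _MIN_SHARED:
        raise ValueError(f"need at least {_MIN_SHARED} shared variants")
    ell = panel.ld_score
    if np.ptp(ell) < 1e-12:
        raise ValueError("all LD scores equal: regression design is collinear")
    z1 = stats1.z if stats1.z is not None else np.sqrt(stats1.chisq)
    z2 = stats2.z if stats2.z is not None else np.sqrt(stats2.chisq)
    y = z1 * z2
    w = panel.snp_weight
    scale = panel.n_snps / np.sqrt(float(np.mean(stats1.n)) *
                                   float(np.mean(stats2.n)))
    cov_hat = _ldsc_slope(y, ell, w) * scale

    # delete-one-block jackknife over LD blocks, via sufficient statistics
    slices = list(panel.block_slices().values())
    n_blocks = len(slices)
    if n_blocks < 2:
        raise ValueError("jackknife needs at least 2 LD blocks")
    A, b = _ldsc_suffstats(y, ell, w)
    A_tot, b_tot = A.sum(axis=1), b.sum(axis=1)
    pseudo = np.empty(n_blocks)
    for i, sl in enumerate(slices):
        A_i = A_tot - A[:, sl].sum(axis=1)
        b_i = b_tot - b[:, sl].sum(axis=1)
        pseudo[i] = _slope_from_suffstats(A_i, b_i) * scale
    var = (n_blocks - 1) / n_blocks * float(np.sum((pseudo - pseudo.mean()) ** 2))
    se = np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(cov_hat) / se) if se > 0 else np.nan
    return cov_hat, var, float(p)


def estimate_genetic_covariance_matrix(stats: list[SummaryStats],
                                       panel: SNPPanel,
                                       labels: list[str] | None = None,
                                       ) -> GeneticCovarianceMatrix:
    """Pairwise cross-trait LDSC over a list of traits (diagonal = univariate)."""
    k = len(stats)
    labels = labels or [f"met_{i + 1:02d}" for i in range(k)]
    cov = np.zeros((k, k))
    var = np.zeros((k, k))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i, k):
            c, v, pp = cross_trait_ldsc(stats[i], stats[j], panel)
            cov[i, j] = cov[j, i] = c
            var[i, j] = var[j, i] = v
            p[i, j] = p[j, i] = pp
    return GeneticCovarianceMatrix(cov=cov, var_of_est=var, p=p, labels=labels)


def sparsify(covmat: GeneticCovarianceMatrix,
             p_threshold: float = 0.05) -> GeneticCovarianceMatrix:
    """Zero off-diagonal entries not nominally significant (strict P > 0.05)."""
    cov = covmat.cov.copy()
    zeroed = covmat.zeroed.copy()
    off = ~np.eye(cov.shape[0], dtype=bool)
    drop = off & (covmat.p > p_threshold)
    cov[drop] = 0.0
    zeroed |= drop
    return GeneticCovarianceMatrix(cov=cov, var_of_est=covmat.var_of_est,
                                   p=covmat.p, labels=covmat.labels,
                                   zeroed=zeroed, bent=covmat.bent)


def weighted_bending(covmat: GeneticCovarianceMatrix, eps: float = 1e-8,
                     step: float = 0.5, max_iter: int = 1000,
                     ) -> GeneticCovarianceMatrix:
    """Precision-weighted iterative bending to positive semidefiniteness.

    Each iteration projects the current matrix to the PSD cone by flooring
    negative eigenvalues, then moves each off-diagonal entry a fraction
    ``step * mobility_ij`` of the way toward the projection, where the
    mobility is proportional to the entry's estimation variance (precise
    entries move least; the diagonal never moves).  A PSD input is returned
    unchanged.  Raises after ``max_iter`` without convergence.
    """
    M0 = covmat.cov.copy()
    M = M0.copy()
    k = M.shape[0]
    if np.linalg.eigvalsh(M).min() >= -eps:
        return GeneticCovarianceMatrix(cov=M, var_of_est=covmat.var_of_est,
                                       p=covmat.p, labels=covmat.labels,
                                       zeroed=covmat.zeroed, bent=False,
                                       mean_abs_change=0.0)
    var = np.asarray(covmat.var_of_est, dtype=float)
    off = ~np.eye(k, dtype=bool)
    v = np.where(var > 0, var, np.nanmax(var[var > 0]) if np.any(var > 0) else 1.0)
    mobility = np.zeros_like(M)
    mobility[off] = v[off] / v[off].max()
    for _ in range(max_iter):
        lam, V = np.linalg.eigh(M)
        if lam.min() >= -eps:
            change = float(np.mean(np.abs(M - M0)))
            return GeneticCovarianceMatrix(cov=M, var_of_est=covmat.var_of_est,
                                           p=covmat.p, labels=covmat.labels,
                                           zeroed=covmat.zeroed, bent=True,
                                           mean_abs_change=change)
        floor = max(abs(lam).max() * 1e-6, eps)
        target = (V * np.maximum(lam, floor)) @ V.T
        M = M + step * mobility * (target - M)
        M = 0.5 * (M + M.T)
    lam = np.linalg.eigvalsh(M)
    raise RuntimeError(f"bending did not converge in {max_iter} iterations; "
                       f"min eigenvalue {lam.min():.3e}")


def cov_to_corr(covmat: GeneticCovarianceMatrix) -> CorrelationContext:
    """Normalize a (bent) covariance matrix to a correlation matrix."""
    d = np.diag(covmat.cov)
    if np.any(d <= 0):
        raise ValueError("covariance diagonal must be positive")
    s = 1.0 / np.sqrt(d)
    sigma = covmat.cov * np.outer(s, s)
    np.fill_diagonal(sigma, 1.0)
    sigma = np.clip(sigma, -1.0, 1.0)
    # bending stops at min eig >= -1e-8 on the covariance scale; the
    # normalization can scale that just past the correlation-scale tolerance
    return CorrelationContext.from_estimate(sigma, list(covmat.labels))


# ---------------------------------------------------------------------------
# matrix TSV round-trip
# ---------------------------------------------------------------------------

def write_matrix(mat: np.ndarray, labels: list[str], path: str) -> None:
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g")


def read_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), list(df.index)
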