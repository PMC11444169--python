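"""Correlation-adjusted association and heterogeneity statistics.

Metabolite-level quantities (selection strength, conservation rank, causal
effect) are not independent across metabolites; all tests here propagate the
metabolite correlation matrix Sigma.

* ``adjusted_slope``: the through-origin slope of standardized y on
  standardized x.  The OLS estimator ``r_hat = (y'x)/(x'x)`` stays unbiased
  under correlated errors ``eps ~ N(0, sigma2 Sigma)``, but its variance
  becomes ``sigma2 * x' Sigma x / (x'x)**2``; only the variance is adjusted.
* ``modified_cochran_q``: heterogeneity of class-mean selection estimates.
  With ``alpha_hat ~ N(., Omega)``, ``Omega = diag(SE) Sigma diag(SE)``, the
  class means ``m = V alpha_hat`` have covariance ``W = V Omega V'``; the
  centered means ``d = m - mean(m)`` have covariance ``D W D`` (D the
  centering projector), and ``Q = d' (D W D)^+ d`` follows chi-square with
  K - 1 degrees of freedom under homogeneity.  The pseudoinverse accommodates
  the one-dimensional rank deficiency that centering introduces.
* ``class_vs_rest``: contrast of a class mean against the mean of all other
  metabolites, with null variance ``w' Omega w``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gencorr import CorrelationContext

__all__ = ["AdjustedSlopeResult", "ClassAssignment", "HeterogeneityResult",
           "adjusted_slope", "modified_cochran_q", "class_vs_rest",
           "benjamini_hochberg"]


@dataclass
class AdjustedSlopeResult:
    r_hat: float
    se: float
    sigma2: float
    p: float
    n: int
    degenerate: bool = False


@dataclass
class ClassAssignment:
    """Metabolite -> class labels with membership bookkeeping."""

    labels: pd.Series  # index: metabolite, values: class label

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels)
        if self.labels.isna().any():
            raise ValueError("every metabolite needs a class label")
        self.classes = list(dict.fromkeys(self.labels))
        self.sizes = self.labels.value_counts().to_dict()

    @property
    def k(self) -> int:
        return len(self.classes)

    def membership_matrix(self) -> np.ndarray:
        """Row i = v(i): 1/n_i on members of class i, 0 elsewhere."""
        V = np.zeros((self.k, len(self.labels)))
        arr = self.labels.to_numpy()
        for i, cls in enumerate(self.classes):
            mask = arr == cls
            V[i, mask] = 1.0 / mask.sum()
        return V

    def contrast_vector(self, target_class) -> np.ndarray:
        """1/n_i on members, -1/n_(-i) on the complement."""
        arr = self.labels.to_numpy()
        mask = arr == target_class
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        if n_in == 0:
            raise ValueError(f"class {target_class!r} is empty")
        if n_out == 0:
            raise ValueError("contrast needs metabolites outside the class")
        w = np.where(mask, 1.0 / n_in, -1.0 / n_out)
        return w


@dataclass
class HeterogeneityResult:
    class_means: np.ndarray
    overall_mean: float
    omega: np.ndarray
    w_matrix: np.ndarray
    q: float
    df: int
    p: float
    classes: list


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance input cannot be standardized")
    return (v - v.mean()) / sd


def adjusted_slope(y: np.ndarray, x: np.ndarray,
                   sigma: CorrelationContext | np.ndarray) -> AdjustedSlopeResult:
    """Slope of standardized y on standardized x with Sigma-adjusted variance."""
    S = sigma.sigma if isinstance(sigma, CorrelationContext) else np.asarray(sigma)
    ys = _standardize(y)
    xs = _standardize(x)
    n = xs.size
    if S.shape != (n, n):
        raise ValueError("Sigma dimension must match the data length")
    xtx = float(xs @ xs)
    r_hat = float(ys @ xs) / xtx
    rss = float(np.sum((ys - r_hat * xs) ** 2))
    sigma2 = rss / (n - 1)
    var = sigma2 * float(xs @ S @ xs) / xtx ** 2
    if var <= 0:
        # perfect fit: slope exact, P degenerate by convention
        return AdjustedSlopeResult(r_hat=r_hat, se=0.0, sigma2=sigma2, p=0.0,
                                   n=n, degenerate=True)
    se = float(np.sqrt(var))
    p = 2.0 * sps.norm.sf(abs(r_hat) / se)
    return AdjustedSlopeResult(r_hat=r_hat, se=se, sigma2=sigma2, p=float(p), n=n)


def build_omega(se: np.ndarray, sigma: CorrelationContext | np.ndarray) -> np.ndarray:
    S = sigma.sigma if isinstance(sigma, CorrelationContext) else np.asarray(sigma)
    se = np.asarray(se, dtype=float)
    return S * np.outer(se, se)


def modified_cochran_q(alpha_hat: np.ndarray, se: np.ndarray,
                       sigma: CorrelationContext | np.ndarray,
                       classes: ClassAssignment,
                       overall: str = "class_means") -> HeterogeneityResult:
    """Correlation-adjusted Cochran's Q across metabolite classes.

    ``overall`` picks the centering mean: ``"class_means"`` (unweighted mean
    of class means, the default) or ``"metabolites"`` (mean over all
    metabolites).  Q is referred to chi-square with K - 1 degrees of freedom.
    """
    if classes.k < 2:
        raise ValueError("heterogeneity needs at least 2 classes")
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    omega = build_omega(se, sigma)
    V = classes.membership_matrix()
    m = V @ alpha_hat
    K = classes.k
    if overall == "class_means":
        abar = float(m.mean())
        d = m - abar
        D = np.eye(K) - np.full((K, K), 1.0 / K)
    elif overall == "metabolites":
        abar = float(alpha_hat.mean())
        d = m - abar
        u = np.full((len(alpha_hat), 1), 1.0 / len(alpha_hat))
        D = None  # handled below
    else:
        raise ValueError("overall must be 'class_means' or 'metabolites'")
    W = V @ omega @ V.T
    if overall == "class_means":
        cov_d = D @ W @ D.T
    else:
        A = V - np.ones((K, 1)) @ u.T
        cov_d = A @ omega @ A.T
    lam = np.linalg.eigvalsh(cov_d)
    rank_def = int(np.sum(lam < lam.max() * 1e-10))
    if rank_def > 1:
        raise ValueError("covariance of centered class means is rank deficient "
                         f"beyond centering (eigenvalues {np.sort(lam)[:3]})")
    q = float(d @ np.linalg.pinv(cov_d, rcond=1e-10) @ d)
    df = K - 1
    p = float(sps.chi2.sf(q, df))
    return HeterogeneityResult(class_means=m, overall_mean=abar, omega=omega,
                               w_matrix=W, q=q, df=df, p=p,
                               classes=list(classes.classes))


def class_vs_rest(alpha_hat: np.ndarray, se: np.ndarray,
                  sigma: CorrelationContext | np.ndarray,
                  classes: ClassAssignment, target_class) -> tuple[float, float]:
    """Test a class's mean selection strength against all other metabolites.

    Returns ``(t, p)`` where ``t = w' alpha_hat`` and the two-sided P uses the
    null variance ``w' Omega w``.
    """
    w = classes.contrast_vector(target_class)
    omega = build_omega(se, sigma)
    t = float(w @ np.asarray(alpha_hat, dtype=float))
    var = float(w @ omega @ w)
    if var <= 0:
        raise ValueError("null variance of the contrast is nonpositive")
    p = 2.0 * sps.norm.sf(abs(t) / np.sqrt(var))
    return t, float(p)


def benjamini_hochberg(p: np.ndarray, fdr: float = 0.05) -> np.ndarray:
    """Step-up FDR rejection flags at level ``fdr``."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    thresh = fdr * (np.arange(1, n + 1)) / n
    below = p[order] <= thresh
    flags = np.zeros(n, dtype=bool)
    if below.any():
        kmax = np.max(np.nonzero(below)[0])
        flags[order[:kmax + 1]] = True
    return flags
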