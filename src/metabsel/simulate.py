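"""Synthetic-data generators for every pipeline input.

All generators are seeded and reproducible: the same spec and seed produce
byte-identical output.  Effect sizes live on the per-allele scale ``b``;
standardized effects are ``b * sqrt(2 f (1 - f))``, and the realized
heritability of an effect vector is ``sum_j b_j**2 * 2 f_j (1 - f_j)``.

Generative models
-----------------
* ``simulate_effects_alpha`` draws causal effects under the MAF/LD-dependent
  architecture ``E[b_j**2] = c * w_j * [2 f_j (1 - f_j)]**alpha`` with ``c``
  fixed so the expected total heritability equals ``h2``.  ``alpha < 0``
  encodes stabilizing selection (rarer variants carry larger effects).
* ``simulate_effects_eyre_walker`` couples effect sizes to a gamma-distributed
  selection coefficient ``S`` and re-draws MAFs so heterozygosity falls with
  ``S``; in the strong-coupling limit every variant contributes equal expected
  heritability, the architecture the alpha model maps to ``alpha = -1``.
* ``simulate_sumstats`` draws marginal z-scores blockwise from
  ``N(sqrt(n) R b*, R)`` — LD dilution enters through ``R``.
* ``simulate_metabolite_set`` shares causal variants across traits and mixes
  per-variant effect draws through the Cholesky factor of a genetic
  correlation matrix.
* ``simulate_mr_dataset`` builds instrument/outcome effect pairs with a known
  causal effect ``theta``.
* ``simulate_bm_traits`` draws tip values of a Brownian motion on a rooted
  tree with known diffusion rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import SNPPanel
from .sumstats import SummaryStats

__all__ = [
    "ArchitectureSpec", "EyreWalkerSpec", "MetabolitePanelSpec", "MRDataset",
    "simulate_effects_alpha", "simulate_effects_eyre_walker",
    "simulate_sumstats", "simulate_metabolite_set", "simulate_mr_dataset",
    "simulate_bm_traits", "random_tree", "realized_h2",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Genetic architecture: heritability, selection strength, polygenicity."""

    h2: float
    alpha: float
    n_samples: int
    prop_causal: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must lie in [0, 1]")
        if not (0.0 < self.prop_causal <= 1.0):
            raise ValueError("prop_causal must lie in (0, 1]")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")


@dataclass
class EyreWalkerSpec:
    """Effect sizes coupled to a selection coefficient S ~ Gamma(shape, scale).

    ``b = effect_scale * S**tau * (1 + eps) * sign`` with ``eps ~ N(0, noise_sd**2)``
    and a random sign.  ``maf_coupling`` (kappa >= 0) controls how strongly
    heterozygosity decreases with the effect size: with
    ``gamma = kappa / (1 + kappa)`` the target heterozygosity is
    ``h_j ∝ h_base_j**(1-gamma) * (b_j**2)**(-gamma)``.  At ``gamma = 1``
    (``maf_coupling = inf``, the strong-selection limit) ``b_j**2 * h_j`` is
    constant across variants, the frequency-independent per-SNP-heritability
    architecture that the alpha model identifies as ``alpha = -1``.
    """

    tau: float = 0.5
    s_shape: float = 1.0
    s_scale: float = 1.0
    effect_scale: float = 1.0
    noise_sd: float = 0.0
    maf_coupling: float = 0.0
    h2: float | None = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau < 0 or self.maf_coupling < 0:
            raise ValueError("tau and maf_coupling must be nonnegative")
        if self.s_shape <= 0 or self.s_scale <= 0:
            raise ValueError("gamma parameters must be positive")
        if self.effect_scale <= 0 or self.noise_sd < 0:
            raise ValueError("effect_scale > 0 and noise_sd >= 0 required")

    @property
    def gamma(self) -> float:
        if np.isinf(self.maf_coupling):
            return 1.0
        return self.maf_coupling / (1.0 + self.maf_coupling)

    @classmethod
    def strong_selection_limit(cls, seed: int = 0, **kw) -> "EyreWalkerSpec":
        """Preset for the S -> infinity limit (alpha -> -1)."""
        kw.setdefault("tau", 0.5)
        return cls(maf_coupling=np.inf, seed=seed, **kw)


@dataclass
class MetabolitePanelSpec:
    """A set of genetically correlated metabolite traits on one SNP panel."""

    n_metabolites: int
    genetic_corr: np.ndarray
    per_metabolite_arch: list[ArchitectureSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        G = np.asarray(self.genetic_corr, dtype=float)
        if G.shape != (self.n_metabolites, self.n_metabolites):
            raise ValueError("genetic_corr shape mismatch")
        if not np.allclose(G, G.T, atol=1e-10) or not np.allclose(np.diag(G), 1.0):
            raise ValueError("genetic_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(G).min() < -1e-8:
            raise ValueError("genetic_corr must be positive semidefinite")
        self.genetic_corr = G
        if len(self.per_metabolite_arch) != self.n_metabolites:
            raise ValueError("need one ArchitectureSpec per metabolite")


# ---------------------------------------------------------------------------
# effect-size generators
# ---------------------------------------------------------------------------

def realized_h2(panel: SNPPanel, effects: np.ndarray) -> float:
    """Realized heritability ``sum_j b_j**2 * 2 f_j (1 - f_j)``."""
    return float(np.sum(effects ** 2 * panel.heterozygosity))


def _causal_mask(n_snps: int, prop_causal: float, rng: np.random.Generator) -> np.ndarray:
    m = int(round(prop_causal * n_snps))
    if m < 1:
        raise ValueError("prop_causal * n_snps must be >= 1")
    idx = rng.choice(n_snps, size=m, replace=False)
    mask = np.zeros(n_snps, dtype=bool)
    mask[idx] = True
    return mask


def simulate_effects_alpha(panel: SNPPanel, spec: ArchitectureSpec,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-allele effects under the MAF/LD-dependent architecture.

    Causal variants (a uniform subset of size ``round(prop_causal * n_snps)``)
    receive ``b_j ~ N(0, c * w_j * h_j**alpha)`` with ``h_j = 2 f_j (1 - f_j)``
    and ``c`` solving ``sum_causal c * w_j * h_j**(alpha+1) = h2``, so the
    expected realized heritability is exactly ``h2``.  Non-causal effects are
    exactly zero; ``h2 = 0`` yields the all-zero vector.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.h2 == 0.0:
        return np.zeros(panel.n_snps)
    mask = _causal_mask(panel.n_snps, spec.prop_causal, rng)
    het = panel.heterozygosity
    shape = panel.snp_weight * het ** spec.alpha
    c = spec.h2 / np.sum(shape[mask] * het[mask])
    b = np.zeros(panel.n_snps)
    b[mask] = rng.normal(0.0, np.sqrt(c * shape[mask]))
    return b


def simulate_effects_eyre_walker(panel: SNPPanel, spec: EyreWalkerSpec,
                                 ) -> tuple[SNPPanel, np.ndarray]:
    """Draw effects under the selection-coefficient coupling; MAFs are re-drawn.

    Returns a *new* panel (same LD structure, updated MAFs) together with the
    per-allele effect vector, rescaled to total heritability ``spec.h2`` when
    that field is set.  In the strong-coupling limit ``b_j**2 * 2 f_j (1-f_j)``
    is constant across variants.
    """
    rng = np.random.default_rng(spec.seed)
    n = panel.n_snps
    S = rng.gamma(spec.s_shape, spec.s_scale, size=n)
    eps = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    sign = rng.choice([-1.0, 1.0], size=n)
    b = spec.effect_scale * S ** spec.tau * (1.0 + eps) * sign
    b[np.abs(b) < 1e-300] = 1e-300  # keep b**2 invertible for the coupling

    gamma = spec.gamma
    h_base = panel.heterozygosity[rng.permutation(n)]  # re-drawn baseline
    log_h = (1.0 - gamma) * np.log(h_base) - gamma * np.log(b ** 2)
    log_h = log_h - log_h.max() + np.log(0.5)  # scale so max heterozygosity = 0.5
    het = np.exp(log_h)
    het = np.clip(het, 1e-6, 0.5)
    maf = (1.0 - np.sqrt(1.0 - 2.0 * het)) / 2.0

    new_panel = SNPPanel(variant_id=panel.variant_id.copy(), maf=maf,
                         block_id=panel.block_id.copy(),
                         ld_block_corr={b_: M.copy() for b_, M in panel.ld_block_corr.items()},
                         ld_score=panel.ld_score.copy(),
                         snp_weight=panel.snp_weight.copy(),
                         annotations=panel.annotations)
    if spec.h2 is not None:
        tot = realized_h2(new_panel, b)
        b = b * np.sqrt(spec.h2 / tot)
    return new_panel, b


# ---------------------------------------------------------------------------
# marginal summary statistics
# ---------------------------------------------------------------------------

def simulate_sumstats(panel: SNPPanel, effects: np.ndarray, n: int,
                      seed: int = 0) -> SummaryStats:
    """Marginal z-scores drawn blockwise from ``N(sqrt(n) R b*, R)``.

    ``b*`` is the standardized-scale effect vector; ``R`` the block LD
    matrix.  The chi-square statistic ``S_j = z_j**2`` is attached together
    with the (constant) sample size.
    """
    if n <= 0:
        raise ValueError("sample size must be positive")
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (panel.n_snps,):
        raise ValueError("effects length must match the panel")
    rng = np.random.default_rng(seed)
    bstar = effects * np.sqrt(panel.heterozygosity)
    z = np.empty(panel.n_snps)
    for b, sl in panel.block_slices().items():
        R = panel.ld_block_corr[b]
        mean = np.sqrt(n) * R @ bstar[sl]
        if R.shape[0] == 1:
            z[sl] = mean + rng.standard_normal(1)
        else:
            L = np.linalg.cholesky(R + 1e-10 * np.eye(R.shape[0]))
            z[sl] = mean + L @ rng.standard_normal(R.shape[0])
    return SummaryStats(variant_id=panel.variant_id.copy(), chisq=z ** 2,
                        n=np.full(panel.n_snps, float(n)), z=z)


def simulate_metabolite_set(spec: MetabolitePanelSpec, panel: SNPPanel,
                            ) -> tuple[list[SummaryStats], np.ndarray, np.ndarray]:
    """Correlated metabolite traits sharing causal variants on one panel.

    Per causal variant a k-vector ``u ~ N(0, Sigma_g)`` is drawn (Cholesky
    mixing) and scaled by each metabolite's own architecture, so traits with
    identical alpha have genetic correlation ``Sigma_g`` exactly.  Summary
    statistics use independent GWAS noise per metabolite (no sample overlap).

    Returns ``(stats_list, true_alpha, Sigma_g)``.
    """
    master = np.random.default_rng(spec.per_metabolite_arch[0].seed)
    k = spec.n_metabolites
    mask = _causal_mask(panel.n_snps, spec.per_metabolite_arch[0].prop_causal, master)
    m = int(mask.sum())
    L = np.linalg.cholesky(spec.genetic_corr + 1e-10 * np.eye(k))
    U = master.standard_normal((m, k)) @ L.T
    het = panel.heterozygosity
    stats: list[SummaryStats] = []
    for i, arch in enumerate(spec.per_metabolite_arch):
        shape = panel.snp_weight * het ** arch.alpha
        c = arch.h2 / np.sum(shape[mask] * het[mask]) if arch.h2 > 0 else 0.0
        b = np.zeros(panel.n_snps)
        b[mask] = np.sqrt(c * shape[mask]) * U[:, i]
        sub_seed = int(master.integers(0, 2 ** 31 - 1))
        stats.append(simulate_sumstats(panel, b, arch.n_samples, seed=sub_seed))
    true_alpha = np.array([a.alpha for a in spec.per_metabolite_arch])
    return stats, true_alpha, spec.genetic_corr


# ---------------------------------------------------------------------------
# Mendelian-randomization datasets
# ---------------------------------------------------------------------------

@dataclass
class MRDataset:
    """Instrument-level effect pairs with known causal effect ``theta``."""

    variant_id: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    theta: float


def simulate_mr_dataset(n_instruments: int, theta: float,
                        exposure_h2_per_instr: float = 0.01,
                        n_exp: int = 100_000, n_out: int = 100_000,
                        pleiotropy_sd: float = 0.0, seed: int = 0) -> MRDataset:
    """Two-sample MR dataset with causal effect ``theta``.

    True instrument effects ``g ~ N(0, exposure_h2_per_instr)``; observed
    exposure effects add estimation noise with ``se = 1/sqrt(n_exp)``; outcome
    effects are ``theta * g`` plus pleiotropic noise plus estimation noise with
    ``se = 1/sqrt(n_out)``.  Alleles are assigned for harmonization testing.
    """
    if n_instruments < 1:
        raise ValueError("need at least one instrument")
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, np.sqrt(exposure_h2_per_instr), size=n_instruments)
    se_x = np.full(n_instruments, 1.0 / np.sqrt(n_exp))
    se_y = np.full(n_instruments, 1.0 / np.sqrt(n_out))
    bx = g + rng.normal(0.0, se_x)
    pleio = rng.normal(0.0, pleiotropy_sd, size=n_instruments) \
        if pleiotropy_sd > 0 else 0.0
    by = theta * g + pleio + rng.normal(0.0, se_y)
    pairs = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")], dtype=object)
    choice = rng.integers(0, len(pairs), size=n_instruments)
    return MRDataset(
        variant_id=np.array([f"rs{j + 1}" for j in range(n_instruments)], dtype=object),
        beta_exposure=bx, se_exposure=se_x, beta_outcome=by, se_outcome=se_y,
        effect_allele=pairs[choice, 0], other_allele=pairs[choice, 1],
        theta=theta)


# ---------------------------------------------------------------------------
# Brownian motion on a tree
# ---------------------------------------------------------------------------

def simulate_bm_traits(tree, rate: float, root_value: float = 0.0,
                       seed: int = 0) -> "pd.Series":
    """Tip values of a Brownian motion with diffusion rate ``rate``.

    Tips are multivariate normal with mean ``root_value`` and covariance
    ``rate * C`` where ``C`` is the shared-branch-length matrix of the tree.
    Branch lengths must be positive.
    """
    import pandas as pd

    from .conservation import phylo_covariance

    if rate < 0:
        raise ValueError("rate must be nonnegative")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    C = phylo_covariance(tree, labels)
    for e in tree.preorder_edge_iter():
        if e.tail_node is not None and (e.length is None or e.length <= 0):
            raise ValueError("tree must have positive branch lengths")
    rng = np.random.default_rng(seed)
    if rate == 0:
        vals = np.full(len(labels), root_value)
    else:
        L = np.linalg.cholesky(rate * C + 1e-12 * np.eye(len(labels)))
        vals = root_value + L @ rng.standard_normal(len(labels))
    return pd.Series(vals, index=labels)


def random_tree(n_tips: int, seed: int = 0, branch_low: float = 0.2,
                branch_high: float = 1.0):
    """Random rooted binary tree with uniform branch lengths (Newick capable).

    Built by repeatedly joining two uniformly chosen subtrees; species are
    labelled ``sp_01`` upward.
    """
    import dendropy

    rng = np.random.default_rng(seed)
    nodes = [f"sp_{i + 1:02d}:{rng.uniform(branch_low, branch_high):.6f}"
             for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b_ = nodes[i], nodes[j]
        blen = rng.uniform(branch_low, branch_high)
        merged = f"({a},{b_}):{blen:.6f}"
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    newick = nodes[0].rsplit(":", 1)[0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")
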