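"""Canned simulation studies used by the analysis scripts and tests.

Each study fixes its generative conditions (panel size, heritability, sample
size) and varies only the seed, so replicate sets are reproducible and
directly comparable.
"""

from __future__ import annotations

import numpy as np

from .alpha import AlphaFit, profile_alpha
from .panel import simulate_panel
from .simulate import ArchitectureSpec, simulate_effects_alpha, simulate_sumstats

__all__ = ["strong_selection_limit_alpha", "fit_simulated_alpha"]


def fit_simulated_alpha(panel, true_alpha: float, h2: float, n_samples: int,
                        effect_seed: int, noise_seed: int) -> AlphaFit:
    """One replicate: draw effects and marginal statistics, fit the profile."""
    spec = ArchitectureSpec(h2=h2, alpha=true_alpha, n_samples=n_samples,
                            seed=effect_seed)
    b = simulate_effects_alpha(panel, spec)
    stats = simulate_sumstats(panel, b, n_samples, seed=noise_seed)
    return profile_alpha(stats, panel)


def strong_selection_limit_alpha(seeds, n_snps: int = 5000, h2: float = 0.5,
                                 n_samples: int = 50_000,
                                 maf_low: float = 0.01, maf_high: float = 0.5,
                                 ) -> np.ndarray:
    """Fitted alpha per replicate under frequency-independent per-SNP h2.

    Squared per-allele effects scale as 1 / (2 f (1 - f)) — the documented
    strong-selection limit of the selection-coefficient coupling — on an
    LD-free panel with unit weights, so the expected fitted alpha is -1.
    One panel, effect draw and GWAS noise draw per seed.
    """
    out = []
    for s in seeds:
        panel = simulate_panel(n_snps, n_snps, maf_low, maf_high, 0.0,
                               seed=int(s))
        fit = fit_simulated_alpha(panel, true_alpha=-1.0, h2=h2,
                                  n_samples=n_samples,
                                  effect_seed=int(s) + 1,
                                  noise_seed=int(s) + 2)
        out.append(fit.alpha_hat)
    return np.asarray(out)
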