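"""Inverse-variance-weighted Mendelian randomization.

Exposure (metabolite) and outcome (complex trait) summary statistics are
joined on variant, harmonized to a common effect allele, and combined with
fixed-effect first-order weights:

    theta_hat = sum_i bx_i by_i / se_yi**2 / sum_i bx_i**2 / se_yi**2
    SE        = (sum_i bx_i**2 / se_yi**2) ** (-1/2)

With a single instrument this is exactly the Wald ratio ``by / bx`` with
``SE = se_y / |bx|``.  Causal estimates larger than 0.5 in absolute value are
treated as exposure/outcome overlap artefacts and excluded from downstream
scores; the per-metabolite importance score is the total absolute causal
effect across traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["InstrumentSet", "CausalEstimate", "harmonize", "ivw_estimate",
           "filter_large_effects", "importance_scores", "select_instruments"]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class InstrumentSet:
    variant_id: np.ndarray
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    n_dropped_palindromic: int = 0
    n_dropped_mismatch: int = 0

    def __post_init__(self) -> None:
        if np.any(self.se_exposure <= 0) or np.any(self.se_outcome <= 0):
            raise ValueError("standard errors must be positive")
        if len(set(self.variant_id)) != len(self.variant_id):
            raise ValueError("duplicate variant_id in instrument set")

    @property
    def n_instruments(self) -> int:
        return len(self.variant_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant_id": self.variant_id,
            "beta": self.beta_exposure, "se": self.se_exposure,
            "beta_outcome": self.beta_outcome, "se_outcome": self.se_outcome,
            "effect_allele": self.effect_allele,
            "other_allele": self.other_allele})


@dataclass
class CausalEstimate:
    theta_hat: float
    se: float
    p: float
    n_instruments: int
    filtered_overlap: bool = False


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in _PALINDROMIC


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> InstrumentSet:
    """Join exposure and outcome records on variant and align effect alleles.

    Both frames need columns ``variant_id, beta, se, effect_allele,
    other_allele``.  Outcome effects are sign-flipped when its effect allele
    is the exposure's other allele; strand-ambiguous palindromic variants
    (A/T, C/G) and allele-incompatible records are dropped with logged counts.
    Harmonizing an already-harmonized set is a no-op.
    """
    merged = exposure.merge(outcome, on="variant_id", suffixes=("_x", "_y"))
    if merged.empty:
        raise ValueError("no shared variants between exposure and outcome")
    keep_rows, flip = [], []
    n_pal = n_mis = 0
    for _, r in merged.iterrows():
        ex_a1, ex_a2 = r["effect_allele_x"], r["other_allele_x"]
        ou_a1, ou_a2 = r["effect_allele_y"], r["other_allele_y"]
        if _is_palindromic(ex_a1, ex_a2):
            n_pal += 1
            continue
        if (ou_a1, ou_a2) == (ex_a1, ex_a2):
            flip.append(1.0)
        elif (ou_a1, ou_a2) == (ex_a2, ex_a1):
            flip.append(-1.0)
        else:
            # allow strand flips for non-palindromic variants
            ca1, ca2 = _COMPLEMENT.get(ou_a1, "?"), _COMPLEMENT.get(ou_a2, "?")
            if (ca1, ca2) == (ex_a1, ex_a2):
                flip.append(1.0)
            elif (ca1, ca2) == (ex_a2, ex_a1):
                flip.append(-1.0)
            else:
                n_mis += 1
                continue
        keep_rows.append(r)
    if not keep_rows:
        raise ValueError("no harmonizable variants remain")
    if n_pal or n_mis:
        log.info("harmonize: dropped %d palindromic and %d allele-mismatched "
                 "variants", n_pal, n_mis)
    kept = pd.DataFrame(keep_rows)
    sign = np.asarray(flip)
    return InstrumentSet(
        variant_id=kept["variant_id"].to_numpy(dtype=object),
        beta_exposure=kept["beta_x"].to_numpy(float),
        se_exposure=kept["se_x"].to_numpy(float),
        beta_outcome=sign * kept["beta_y"].to_numpy(float),
        se_outcome=kept["se_y"].to_numpy(float),
        effect_allele=kept["effect_allele_x"].to_numpy(dtype=object),
        other_allele=kept["other_allele_x"].to_numpy(dtype=object),
        n_dropped_palindromic=n_pal, n_dropped_mismatch=n_mis)


def select_instruments(exposure: pd.DataFrame, p_threshold: float = 5e-8,
                       block: np.ndarray | None = None) -> pd.DataFrame:
    """Genome-wide-significant instruments, LD-pruned to one per block.

    ``exposure`` needs ``beta`` and ``se``; when ``block`` labels are given,
    only the smallest-P variant per block is retained.
    """
    z = exposure["beta"].to_numpy(float) / exposure["se"].to_numpy(float)
    p = 2.0 * sps.norm.sf(np.abs(z))
    df = exposure.assign(_p=p)
    df = df[df["_p"] < p_threshold]
    if block is not None:
        df = df.assign(_blk=np.asarray(block)[df.index])
        df = df.sort_values("_p").groupby("_blk", as_index=False).head(1)
        df = df.drop(columns="_blk")
    return df.drop(columns="_p").reset_index(drop=True)


def ivw_estimate(instruments: InstrumentSet) -> CausalEstimate:
    """Fixed-effect IVW causal estimate with first-order weights."""
    bx = instruments.beta_exposure
    by = instruments.beta_outcome
    sy = instruments.se_outcome
    denom = float(np.sum(bx ** 2 / sy ** 2))
    if denom == 0.0:
        raise ValueError("all instrument-exposure effects are zero")
    theta = float(np.sum(bx * by / sy ** 2)) / denom
    se = denom ** -0.5
    p = 2.0 * sps.norm.sf(abs(theta / se))
    return CausalEstimate(theta_hat=theta, se=se, p=float(p),
                          n_instruments=instruments.n_instruments)


def filter_large_effects(estimates: pd.DataFrame,
                         threshold: float = 0.5) -> pd.DataFrame:
    """Flag causal effects with ``|theta| > threshold`` as overlap artefacts.

    Expects a long-format frame with a ``theta`` column; adds/overwrites a
    boolean ``filtered`` column (strict inequality: exactly ``threshold`` is
    retained).  Flagged entries are excluded by :func:`importance_scores`.
    """
    out = estimates.copy()
    out["filtered"] = out["theta"].abs() > threshold
    n = int(out["filtered"].sum())
    if n:
        log.info("filter_large_effects: flagged %d of %d estimates "
                 "(|theta| > %g)", n, len(out), threshold)
    return out


def importance_scores(estimates: pd.DataFrame) -> pd.Series:
    """Total absolute causal effect per metabolite across traits.

    ``estimates`` is long format with columns ``metabolite, trait, theta`` and
    (after :func:`filter_large_effects`) ``filtered``.  Flagged and missing
    cells are skipped; a metabolite whose cells are all flagged scores 0 with
    a completeness warning.
    """
    df = estimates.copy()
    if "filtered" not in df.columns:
        df["filtered"] = False
    usable = df[~df["filtered"] & df["theta"].notna()]
    scores = usable.groupby("metabolite")["theta"].apply(lambda t: t.abs().sum())
    all_mets = pd.Index(df["metabolite"].unique())
    empty = all_mets.difference(scores.index)
    for m in empty:
        warnings.warn(f"metabolite {m}: every causal estimate filtered or "
                      "missing; importance score set to 0", stacklevel=2)
    return scores.reindex(all_mets, fill_value=0.0).rename("importance")
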