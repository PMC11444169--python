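"""SNP panels: minor allele frequencies, LD-block structure, LD scores and SNP weights.

A :class:`SNPPanel` is the reference object every other stage consumes.  Linkage
disequilibrium is represented block-diagonally: variants are partitioned into
blocks, each block carries a dense correlation matrix ``R`` and the LD score of
variant *j* is the within-block row sum of squared correlations,
``l_j = sum_l r_jl**2`` (self-correlation included, so ``l_j >= 1``).  The SNP
weight defaults to the inverse LD score, ``w_j = 1 / l_j``, which is the weight
entering both the heritability model and the quasi-likelihood.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SNPPanel", "simulate_panel", "write_ld_scores", "read_ld_scores",
           "write_ld_blocks", "read_ld_blocks"]

_EIG_TOL = -1e-8


@dataclass
class SNPPanel:
    """Per-variant MAF, LD-block membership, LD scores, SNP weights and annotations.

    Parameters
    ----------
    variant_id : array of str
    maf : array of float
        Minor allele frequencies, each in (0, 0.5].
    block_id : array of int
        LD-block label per variant.  Variants of one block must be contiguous.
    ld_block_corr : dict mapping block id -> square correlation matrix
    ld_score : array of float
        ``l_j = sum_l r_jl**2`` within the block; always >= 1.
    snp_weight : array of float
        Positive weights ``w_j``; by construction inversely proportional to
        the LD score unless the caller supplies custom weights.
    annotations : optional (n_snps, n_categories) array
        Real-valued annotation loadings for stratified heritability models.
    """

    variant_id: np.ndarray
    maf: np.ndarray
    block_id: np.ndarray
    ld_block_corr: dict[int, np.ndarray]
    ld_score: np.ndarray
    snp_weight: np.ndarray
    annotations: np.ndarray | None = None
    _slices: dict[int, slice] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.maf = np.asarray(self.maf, dtype=float)
        self.block_id = np.asarray(self.block_id, dtype=int)
        self.ld_score = np.asarray(self.ld_score, dtype=float)
        self.snp_weight = np.asarray(self.snp_weight, dtype=float)
        self.validate()

    # -- contracts -------------------------------------------------------
    def validate(self) -> None:
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("MAF must lie in (0, 0.5]")
        if np.any(self.ld_score < 1 - 1e-12):
            raise ValueError("LD scores must be >= 1 (self-correlation included)")
        if np.any(self.snp_weight <= 0):
            raise ValueError("SNP weights must be positive")
        self._slices = {}
        start = 0
        for b, grp in _contiguous_groups(self.block_id):
            self._slices[b] = slice(start, start + grp)
            start += grp
        if start != self.n_snps:
            raise ValueError("block_id labels must be contiguous runs")
        for b, sl in self._slices.items():
            R = np.asarray(self.ld_block_corr[b], dtype=float)
            m = sl.stop - sl.start
            if R.shape != (m, m):
                raise ValueError(f"block {b}: matrix shape {R.shape} != ({m},{m})")
            if not np.allclose(R, R.T, atol=1e-10):
                raise ValueError(f"block {b}: correlation matrix not symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise ValueError(f"block {b}: correlation matrix diagonal != 1")
            if np.linalg.eigvalsh(R).min() < _EIG_TOL:
                raise ValueError(f"block {b}: correlation matrix not PSD")
            self.ld_block_corr[b] = R

    # -- derived quantities ----------------------------------------------
    @property
    def n_snps(self) -> int:
        return self.maf.size

    @property
    def heterozygosity(self) -> np.ndarray:
        """``2 f (1 - f)`` per variant."""
        return 2.0 * self.maf * (1.0 - self.maf)

    def block_slices(self) -> dict[int, slice]:
        return dict(self._slices)

    def subset(self, idx: np.ndarray) -> "SNPPanel":
        """Restrict to variants ``idx``; LD blocks are cut down accordingly."""
        idx = np.asarray(idx)
        keep = np.zeros(self.n_snps, dtype=bool)
        keep[idx] = True
        blocks = {}
        for b, sl in self._slices.items():
            sub = keep[sl]
            if sub.any():
                blocks[b] = self.ld_block_corr[b][np.ix_(sub, sub)]
        R2 = {b: M for b, M in blocks.items()}
        ld = np.concatenate([np.square(M).sum(axis=1) for M in R2.values()]) \
            if R2 else np.array([])
        return SNPPanel(
            variant_id=self.variant_id[keep],
            maf=self.maf[keep],
            block_id=self.block_id[keep],
            ld_block_corr=blocks,
            ld_score=ld,
            snp_weight=1.0 / ld,
            annotations=None if self.annotations is None else self.annotations[keep],
        )


def _contiguous_groups(labels: np.ndarray):
    """Yield (label, run_length) for contiguous runs; error on repeats."""
    seen: set[int] = set()
    i = 0
    n = labels.size
    while i < n:
        b = labels[i]
        if b in seen:
            raise ValueError("block_id labels must be contiguous runs")
        seen.add(int(b))
        j = i
        while j < n and labels[j] == b:
            j += 1
        yield int(b), j - i
        i = j


def simulate_panel(n_snps: int, n_blocks: int, maf_low: float = 0.01,
                   maf_high: float = 0.5, within_block_corr: float | tuple = 0.0,
                   seed: int = 0) -> SNPPanel:
    """Simulate a SNP panel with exchangeable-correlation LD blocks.

    MAFs are drawn uniformly on ``[maf_low, maf_high]``.  Variants are split
    into ``n_blocks`` near-equal contiguous blocks; within each block the
    correlation matrix is exchangeable, ``R = (1 - rho) I + rho 11'``.
    ``within_block_corr`` may be a scalar ``rho`` or a ``(lo, hi)`` pair, in
    which case each block draws its own ``rho`` uniformly — this spreads the
    LD scores across variants, which LD-score regression requires.

    LD scores and inverse-LD-score SNP weights are computed from the block
    matrices.  Same seed, same arguments => byte-identical panel.
    """
    if not (n_snps >= n_blocks >= 1):
        raise ValueError("need n_snps >= n_blocks >= 1")
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, maf_high, size=n_snps)
    sizes = [len(a) for a in np.array_split(np.arange(n_snps), n_blocks)]
    if np.isscalar(within_block_corr):
        rhos = np.full(n_blocks, float(within_block_corr))
    else:
        lo, hi = within_block_corr
        rhos = rng.uniform(lo, hi, size=n_blocks)
    blocks: dict[int, np.ndarray] = {}
    block_id = np.empty(n_snps, dtype=int)
    ld = np.empty(n_snps)
    start = 0
    for b, (m, rho) in enumerate(zip(sizes, rhos)):
        if abs(rho) >= 1 or (m > 1 and rho < -1.0 / (m - 1)):
            raise ValueError(f"block {b}: exchangeable corr {rho} with size {m} is not PSD")
        R = np.full((m, m), rho)
        np.fill_diagonal(R, 1.0)
        blocks[b] = R
        block_id[start:start + m] = b
        ld[start:start + m] = 1.0 + (m - 1) * rho ** 2
        start += m
    vid = np.array([f"rs{j + 1}" for j in range(n_snps)], dtype=object)
    return SNPPanel(variant_id=vid, maf=maf, block_id=block_id,
                    ld_block_corr=blocks, ld_score=ld, snp_weight=1.0 / ld)


# ---------------------------------------------------------------------------
# text round-trip: LD-score table and per-block matrices with a manifest
# ---------------------------------------------------------------------------

def write_ld_scores(panel: SNPPanel, path: str) -> None:
    df = pd.DataFrame({"SNP": panel.variant_id, "MAF": panel.maf,
                       "L2": panel.ld_score, "WEIGHT": panel.snp_weight,
                       "BLOCK": panel.block_id})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld_scores(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ld_blocks(panel: SNPPanel, directory: str) -> None:
    """One dense text matrix per block plus a ``manifest.tsv``."""
    os.makedirs(directory, exist_ok=True)
    rows = []
    for b, sl in panel.block_slices().items():
        fname = f"block_{b}.txt"
        np.savetxt(os.path.join(directory, fname), panel.ld_block_corr[b],
                   fmt="%.10g")
        rows.append({"BLOCK": b, "FILE": fname, "N_SNPS": sl.stop - sl.start})
    pd.DataFrame(rows).to_csv(os.path.join(directory, "manifest.tsv"),
                              sep="\t", index=False)


def read_ld_blocks(directory: str) -> dict[int, np.ndarray]:
    manifest = pd.read_csv(os.path.join(directory, "manifest.tsv"), sep="\t")
    out: dict[int, np.ndarray] = {}
    for _, row in manifest.iterrows():
        M = np.loadtxt(os.path.join(directory, row["FILE"]), ndmin=2)
        out[int(row["BLOCK"])] = M
    return out


def read_panel(ld_scores_path: str, blocks_dir: str) -> SNPPanel:
    """Rebuild a panel from its LD-score table and block-matrix directory."""
    df = read_ld_scores(ld_scores_path)
    blocks = read_ld_blocks(blocks_dir)
    return SNPPanel(variant_id=df["SNP"].to_numpy(dtype=object),
                    maf=df["MAF"].to_numpy(float),
                    block_id=df["BLOCK"].to_numpy(int),
                    ld_block_corr=blocks,
                    ld_score=df["L2"].to_numpy(float),
                    snp_weight=df["WEIGHT"].to_numpy(float))
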