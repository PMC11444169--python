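"""GWAS summary statistics: container and tab-separated round-trip.

Statistics are held on the standardized-genotype scale: the marginal z-score
of variant *j* has unit variance under the null and mean ``sqrt(n) * (R b*)_j``
under LD, where ``b*_j = b_j * sqrt(2 f_j (1 - f_j))`` is the standardized
effect.  The chi-square statistic is ``S_j = z_j**2``.  The TSV writer reports
per-allele ``BETA = z / sqrt(n * 2 f (1 - f))`` and its SE so files look like
ordinary GWAS output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SummaryStats", "write_sumstats", "read_sumstats"]


@dataclass
class SummaryStats:
    variant_id: np.ndarray
    chisq: np.ndarray
    n: np.ndarray
    z: np.ndarray | None = None
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.chisq = np.asarray(self.chisq, dtype=float)
        self.n = np.broadcast_to(np.asarray(self.n, dtype=float),
                                 self.chisq.shape).copy()
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
            if not np.allclose(self.chisq, self.z ** 2, atol=1e-8):
                raise ValueError("chisq must equal z**2 where z is present")
        if np.any(self.chisq < 0):
            raise ValueError("chi-square statistics must be nonnegative")
        if np.any(self.n <= 0):
            raise ValueError("sample sizes must be positive")

    @property
    def n_variants(self) -> int:
        return self.chisq.size


def write_sumstats(stats: SummaryStats, maf: np.ndarray, path: str) -> None:
    z = stats.z if stats.z is not None else np.sqrt(stats.chisq)
    het = 2.0 * np.asarray(maf) * (1.0 - np.asarray(maf))
    se = 1.0 / np.sqrt(stats.n * het)
    a1 = stats.effect_allele if stats.effect_allele is not None \
        else np.full(stats.n_variants, "A", dtype=object)
    a2 = stats.other_allele if stats.other_allele is not None \
        else np.full(stats.n_variants, "G", dtype=object)
    pd.DataFrame({"SNP": stats.variant_id, "A1": a1, "A2": a2, "MAF": maf,
                  "BETA": z * se, "SE": se, "Z": z, "N": stats.n.astype(int)}
                 ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_sumstats(path: str) -> SummaryStats:
    df = pd.read_csv(path, sep="\t")
    z = df["Z"].to_numpy(float)
    return SummaryStats(variant_id=df["SNP"].to_numpy(dtype=object),
                        chisq=z ** 2, n=df["N"].to_numpy(float), z=z,
                        effect_allele=df["A1"].to_numpy(dtype=object),
                        other_allele=df["A2"].to_numpy(dtype=object))
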