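"""Cross-species conservation of metabolite concentrations.

For each metabolite in each organ a Brownian-motion model of trait evolution
is fitted across the species phylogeny.  Under Brownian motion with diffusion
rate sigma2 the tip values are multivariate normal with covariance
``sigma2 * C`` where ``C_ij`` is the branch length shared by the root-to-tip
paths of species i and j.  The GLS root estimate and rate are

    mu_hat    = (1' C^-1 x) / (1' C^-1 1)
    sigma2hat = (x - mu_hat 1)' C^-1 (x - mu_hat 1) / (n - 1)

(the n-1 denominator makes the estimator unbiased).  The conservation score
of a metabolite is the inverse rate, 1 / sigma2hat: slowly drifting
concentrations score high.  Per-organ scores are aggregated by ranking within
each organ (average ranks on ties), imputing a metabolite's missing organs
with its median score over measured organs, and taking the median rank across
organs; metabolites measured in fewer than two organs are excluded.
"""

from __future__ import annotations

import logging

import dendropy
import numpy as np
import pandas as pd

__all__ = ["read_tree", "phylo_covariance", "fit_bm_rate",
           "conservation_scores", "aggregate_conservation",
           "write_concentrations", "read_concentrations"]

log = logging.getLogger(__name__)


def read_tree(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=path, schema="newick")


def phylo_covariance(tree: dendropy.Tree, tips: list[str]) -> np.ndarray:
    """Shared-branch-length matrix of the requested tips.

    ``C_ij`` is the total branch length common to the root-to-tip paths of
    tips i and j; the diagonal holds root-to-tip distances.
    """
    leaf_by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    missing = [t for t in tips if t not in leaf_by_label]
    if missing:
        raise ValueError(f"tips not in tree: {missing}")
    # ancestor edge sets keyed by node id, with branch lengths
    paths: list[dict[int, float]] = []
    for t in tips:
        node = leaf_by_label[t]
        path: dict[int, float] = {}
        while node.parent_node is not None:
            path[id(node)] = node.edge.length or 0.0
            node = node.parent_node
        paths.append(path)
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        C[i, i] = sum(paths[i].values())
        for j in range(i + 1, n):
            shared = paths[i].keys() & paths[j].keys()
            C[i, j] = C[j, i] = sum(paths[i][k] for k in shared)
    return C


def fit_bm_rate(C: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """GLS Brownian-rate estimate ``(sigma2_hat, mu_hat)`` from tip values."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 tip values")
    C = np.asarray(C, dtype=float)
    try:
        Cinv_x = np.linalg.solve(C, x)
        Cinv_1 = np.linalg.solve(C, np.ones(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError("phylogenetic covariance matrix is singular") from exc
    mu = float(np.ones(n) @ Cinv_x) / float(np.ones(n) @ Cinv_1)
    resid = x - mu
    sigma2 = float(resid @ np.linalg.solve(C, resid)) / (n - 1)
    return sigma2, mu


def conservation_scores(tree: dendropy.Tree, concentrations: pd.DataFrame,
                        log_transform: bool = True) -> pd.DataFrame:
    """Per-metabolite Brownian rate and inverse-rate score for one organ.

    ``concentrations``: rows = metabolites, columns = species, NaN = missing.
    Each metabolite is fitted on the tree pruned to its measured species
    (the shared-branch-length matrix of a subset is simply the corresponding
    submatrix).  Metabolites with fewer than 3 measured species are skipped;
    zero-rate fits leave the score undefined (NaN).
    """
    species = list(concentrations.columns)
    C_full = phylo_covariance(tree, species)
    rows = []
    for met, vals in concentrations.iterrows():
        mask = vals.notna().to_numpy()
        if mask.sum() < 3:
            log.info("conservation: %s measured in %d < 3 species; skipped",
                     met, int(mask.sum()))
            continue
        x = vals.to_numpy(float)[mask]
        if log_transform:
            if np.any(x <= 0):
                raise ValueError(f"{met}: nonpositive concentration under "
                                 "log transform")
            x = np.log(x)
        C = C_full[np.ix_(mask, mask)]
        sigma2, _ = fit_bm_rate(C, x)
        score = 1.0 / sigma2 if sigma2 > 0 else np.nan
        rows.append({"metabolite": met, "sigma2": sigma2, "score": score,
                     "n_species": int(mask.sum())})
    return pd.DataFrame(rows).set_index("metabolite")


def aggregate_conservation(per_organ_scores: dict[str, pd.Series],
                           organs_subset: list[str] | None = None,
                           ) -> pd.DataFrame:
    """Median-rank aggregation of conservation scores across organs.

    ``per_organ_scores`` maps organ name -> Series of scores indexed by
    metabolite (missing metabolites simply absent or NaN).  Missing organ
    entries are imputed with the metabolite's median score over measured
    organs, scores are ranked within each organ (average ranks on ties,
    ascending: rank 1 = least conserved), and the aggregate is the median
    rank across organs.  Metabolites measured in fewer than two organs are
    excluded.  ``organs_subset`` restricts to a subset (>= 2 organs) for
    leave-one-out analyses.
    """
    organs = list(per_organ_scores) if organs_subset is None else list(organs_subset)
    if len(organs) < 2:
        raise ValueError("aggregation needs at least 2 organs")
    wide = pd.DataFrame({o: per_organ_scores[o] for o in organs})
    n_measured = wide.notna().sum(axis=1)
    wide = wide.loc[n_measured >= 2]
    n_measured = n_measured.loc[wide.index]
    imputed = wide.apply(lambda row: row.fillna(row.median()), axis=1)
    ranks = imputed.rank(axis=0, method="average")
    out = pd.DataFrame({
        "aggregate_median_rank": ranks.median(axis=1),
        "rank_sd": ranks.std(axis=1, ddof=1),
        "n_organs_measured": n_measured.astype(int)})
    for o in organs:
        out[f"rank_{o}"] = ranks[o]
    return out


# ---------------------------------------------------------------------------
# concentration matrix round-trip (one TSV per organ)
# ---------------------------------------------------------------------------

def write_concentrations(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="metabolite",
              float_format="%.10g", na_rep="")


def read_concentrations(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="metabolite")
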