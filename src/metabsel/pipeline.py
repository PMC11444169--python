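"""Configuration-driven orchestration of the synthetic selection analysis.

Stages run in dependency order::

    simulate -> alpha -> gencorr -> mr -> conserve -> stats

``simulate`` writes every input the later stages read (summary statistics,
LD scores and block matrices, a species tree, per-organ concentration
matrices, class labels, MR instrument tables) under the output directory, so
each stage can also be re-run in isolation on previously written files.  The
generative link in the end-to-end run couples a metabolite's selection
strength alpha to (a) its Brownian concentration rate across species
(lower alpha => lower rate => higher conservation) and (b) the scale of its
causal effects on traits (lower alpha => larger absolute effects), mirroring
the two study-level associations the final ``stats`` stage quantifies.

Configuration files are flat ``key = value`` text; unknown keys warn,
malformed values error.  A single global seed is expanded deterministically
into per-stage seeds so partial reruns reproduce stage-for-stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import alpha as alpha_mod
from . import conservation as cons
from . import corrstats, gencorr, mr
from .panel import (SNPPanel, read_panel, simulate_panel, write_ld_blocks,
                    write_ld_scores)
from .simulate import (ArchitectureSpec, MetabolitePanelSpec, random_tree,
                       simulate_bm_traits, simulate_metabolite_set,
                       simulate_mr_dataset)
from .sumstats import read_sumstats, write_sumstats

log = logging.getLogger(__name__)

STAGES = ["simulate", "alpha", "gencorr", "mr", "conserve", "stats"]

CLASS_NAMES = ["nonessential_amino_acids", "essential_amino_acids",
               "acylcarnitines", "phosphatidylcholines",
               "lysophosphatidylcholines", "sphingomyelins",
               "biogenic_amines", "hexoses"]


@dataclass
class RunConfig:
    """All tunables of a pipeline run with study-level defaults."""

    out_dir: str = "pipeline_out"
    seed: int = 1
    stages: str = "all"
    # panel
    n_snps: int = 6000
    n_blocks: int = 300
    maf_low: float = 0.01
    maf_high: float = 0.5
    corr_lo: float = 0.1
    corr_hi: float = 0.8
    unit_weights: int = 1  # 1: GCTA-style flat SNP weights (LDSC well-specified)
    # metabolite set
    n_metabolites: int = 12
    n_classes: int = 4
    h2: float = 0.4
    prop_causal: float = 1.0
    n_samples: int = 50000
    gen_alpha_lo: float = -1.0
    gen_alpha_hi: float = 0.4
    gen_corr: float = 0.3
    # alpha profile
    grid_lo: float = -1.0
    grid_hi: float = 0.5
    grid_step: float = 0.05
    n_tests: int = 97
    # genetic correlation
    p_zero_threshold: float = 0.05
    bending_tol: float = 1e-8
    # MR
    mr_n_traits: int = 8
    mr_n_instruments: int = 30
    mr_filter_threshold: float = 0.5
    mr_base_scale: float = 0.08
    mr_coupling: float = 1.2
    mr_pleiotropy_sd: float = 0.0
    # conservation
    tree_n_tips: int = 26
    organs: str = "brain,heart,kidney,liver"
    rate_base: float = 1.0
    rate_coupling: float = 1.5
    organ_missing_rate: float = 0.15
    cell_missing_rate: float = 0.05
    # stats
    fdr: float = 0.05

    def validate(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if not self.grid_lo < self.grid_hi:
            raise ValueError("grid_lo must be below grid_hi")
        for name in ("p_zero_threshold", "fdr"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.mr_filter_threshold <= 0:
            raise ValueError("mr_filter_threshold must be positive")
        if len(self.organ_list) < 2:
            raise ValueError("need at least 2 organs")
        if self.n_classes < 2 or self.n_classes > len(CLASS_NAMES):
            raise ValueError(f"n_classes must lie in [2, {len(CLASS_NAMES)}]")

    @property
    def organ_list(self) -> list[str]:
        return [o.strip() for o in self.organs.split(",") if o.strip()]

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        return int((self.seed * 1_000_003 + STAGES.index(stage) * 10_007)
                   % (2 ** 31 - 1))

    def path(self, *parts: str) -> str:
        return os.path.join(self.out_dir, *parts)


def validate_config(path: str, **overrides) -> RunConfig:
    """Parse and validate a flat ``key = value`` config file.

    Unknown keys produce warnings (the run proceeds); malformed values and
    out-of-range settings raise.  Keyword overrides (CLI flags) win over file
    values.
    """
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    values: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                warnings.warn(f"{path}:{lineno}: unknown config key {key!r} "
                              "ignored", stacklevel=2)
                continue
            values[key] = _coerce(key, val, fields[key], f"{path}:{lineno}")
    values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**values)
    cfg.validate()
    return cfg


def _coerce(key: str, val: str, typ, where: str):
    try:
        if typ in ("int", int):
            return int(val)
        if typ in ("float", float):
            return float(val)
        return val
    except ValueError as exc:
        raise ValueError(f"{where}: malformed value for {key}: {val!r}") from exc


def _require(path: str, produced_by: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"missing artifact {path!r}; run the '{produced_by}' stage first")
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> dict:
    seed = cfg.stage_seed("simulate")
    rng = np.random.default_rng(seed)
    os.makedirs(cfg.path("panel", "blocks"), exist_ok=True)
    os.makedirs(cfg.path("sumstats"), exist_ok=True)
    os.makedirs(cfg.path("concentrations"), exist_ok=True)
    os.makedirs(cfg.path("mr_truth"), exist_ok=True)

    panel = simulate_panel(cfg.n_snps, cfg.n_blocks, cfg.maf_low, cfg.maf_high,
                           (cfg.corr_lo, cfg.corr_hi), seed=seed)
    if cfg.unit_weights:
        panel.snp_weight = np.ones(panel.n_snps)
    write_ld_scores(panel, cfg.path("panel", "ldscores.tsv"))
    write_ld_blocks(panel, cfg.path("panel", "blocks"))

    k = cfg.n_metabolites
    true_alpha = np.linspace(cfg.gen_alpha_lo, cfg.gen_alpha_hi, k)
    names = [f"met_{i + 1:02d}" for i in range(k)]
    G = np.full((k, k), cfg.gen_corr)
    np.fill_diagonal(G, 1.0)
    archs = [ArchitectureSpec(h2=cfg.h2, alpha=float(a), n_samples=cfg.n_samples,
                              prop_causal=cfg.prop_causal, seed=seed + 1)
             for a in true_alpha]
    spec = MetabolitePanelSpec(n_metabolites=k, genetic_corr=G,
                               per_metabolite_arch=archs)
    stats_list, _, _ = simulate_metabolite_set(spec, panel)
    for name, st in zip(names, stats_list):
        write_sumstats(st, panel.maf, cfg.path("sumstats", f"{name}.tsv"))

    # class labels: contiguous alpha chunks so classes differ in mean alpha
    classes = [CLASS_NAMES[i * cfg.n_classes // k] for i in range(k)]
    pd.DataFrame({"metabolite": names, "class": classes}).to_csv(
        cfg.path("classes.tsv"), sep="\t", index=False)

    # species tree and per-organ concentration matrices under rates coupled
    # to alpha: lower alpha -> lower rate -> higher conservation
    tree = random_tree(cfg.tree_n_tips, seed=seed + 2)
    tree.write(path=cfg.path("tree.nwk"), schema="newick")
    rates = cfg.rate_base * np.exp(cfg.rate_coupling *
                                   (true_alpha - true_alpha.mean()))
    species = [lf.taxon.label for lf in tree.leaf_node_iter()]
    for o_i, organ in enumerate(cfg.organ_list):
        mat = pd.DataFrame(index=names, columns=species, dtype=float)
        for m_i, name in enumerate(names):
            if rng.uniform() < cfg.organ_missing_rate and o_i > 0:
                continue  # metabolite not measured in this organ
            tips = simulate_bm_traits(tree, float(rates[m_i]), root_value=0.0,
                                      seed=int(rng.integers(2 ** 31 - 1)))
            vals = np.exp(tips.to_numpy())  # positive relative concentrations
            drop = rng.uniform(size=len(species)) < cfg.cell_missing_rate
            if drop.sum() > len(species) - 3:
                drop[:] = False
            vals = np.where(drop, np.nan, vals)
            mat.loc[name] = vals
        cons.write_concentrations(mat, cfg.path("concentrations", f"{organ}.tsv"))

    # MR instrument tables: |theta| scale decreases with alpha
    theta_scale = cfg.mr_base_scale * np.exp(-cfg.mr_coupling * true_alpha)
    truth_rows = []
    for m_i, name in enumerate(names):
        for t in range(cfg.mr_n_traits):
            theta = float(rng.normal(0.0, theta_scale[m_i]))
            ds = simulate_mr_dataset(cfg.mr_n_instruments, theta,
                                     pleiotropy_sd=cfg.mr_pleiotropy_sd,
                                     seed=int(rng.integers(2 ** 31 - 1)))
            df = pd.DataFrame({
                "variant_id": ds.variant_id,
                "beta_exposure": ds.beta_exposure, "se_exposure": ds.se_exposure,
                "beta_outcome": ds.beta_outcome, "se_outcome": ds.se_outcome,
                "effect_allele": ds.effect_allele, "other_allele": ds.other_allele})
            df.to_csv(cfg.path("mr_truth", f"{name}_trait_{t + 1:02d}.tsv"),
                      sep="\t", index=False)
            truth_rows.append({"metabolite": name, "trait": f"trait_{t + 1:02d}",
                               "theta_true": theta})
    pd.DataFrame(truth_rows).to_csv(cfg.path("mr_truth", "theta_true.tsv"),
                                    sep="\t", index=False)
    truth = {"names": names, "true_alpha": true_alpha.tolist(),
             "rates": rates.tolist(), "seed": seed}
    with open(cfg.path("truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)
    log.info("simulate: %d SNPs in %d blocks, %d metabolites", cfg.n_snps,
             cfg.n_blocks, k)
    return {"n_snps": cfg.n_snps, "n_metabolites": k}


def _load_panel(cfg: RunConfig) -> SNPPanel:
    return read_panel(_require(cfg.path("panel", "ldscores.tsv"), "simulate"),
                      _require(cfg.path("panel", "blocks"), "simulate"))


def _metabolite_names(cfg: RunConfig) -> list[str]:
    classes = pd.read_csv(_require(cfg.path("classes.tsv"), "simulate"), sep="\t")
    return list(classes["metabolite"])


def stage_alpha(cfg: RunConfig) -> dict:
    panel = _load_panel(cfg)
    names = _metabolite_names(cfg)
    os.makedirs(cfg.path("alpha", "profiles"), exist_ok=True)
    rows = []
    for name in names:
        st = read_sumstats(_require(cfg.path("sumstats", f"{name}.tsv"),
                                    "simulate"))
        fit = alpha_mod.profile_alpha(st, panel, cfg.grid_lo, cfg.grid_hi,
                                      cfg.grid_step)
        pd.DataFrame({"alpha": fit.grid, "loglik": fit.loglik}).to_csv(
            cfg.path("alpha", "profiles", f"{name}.csv"), index=False)
        rows.append({"metabolite": name, **fit.report_row()})
    report = pd.DataFrame(rows)
    report.to_csv(cfg.path("alpha", "alpha_report.tsv"), sep="\t", index=False)
    n_stable = int(report["stable"].sum())
    log.info("alpha: %d of %d metabolites gave stable fits", n_stable, len(names))
    return {"n_stable": n_stable, "n_metabolites": len(names)}


def stage_gencorr(cfg: RunConfig) -> dict:
    panel = _load_panel(cfg)
    names = _metabolite_names(cfg)
    stats = [read_sumstats(_require(cfg.path("sumstats", f"{n}.tsv"),
                                    "simulate")) for n in names]
    covmat = gencorr.estimate_genetic_covariance_matrix(stats, panel, names)
    covmat = gencorr.sparsify(covmat, cfg.p_zero_threshold)
    bent = gencorr.weighted_bending(covmat, eps=cfg.bending_tol)
    ctx = gencorr.cov_to_corr(bent)
    os.makedirs(cfg.path("gencorr"), exist_ok=True)
    gencorr.write_matrix(bent.cov, names, cfg.path("gencorr", "cov.tsv"))
    gencorr.write_matrix(ctx.sigma, names, cfg.path("gencorr", "corr.tsv"))
    sidecar = {"min_eigenvalue": ctx.min_eigenvalue, "bent": bent.bent,
               "mean_abs_change": bent.mean_abs_change,
               "n_zeroed": int(np.sum(bent.zeroed) // 2)}
    with open(cfg.path("gencorr", "gencorr.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    log.info("gencorr: zeroed %d pairs, bent=%s, mean |change| %.4g",
             sidecar["n_zeroed"], bent.bent, bent.mean_abs_change)
    return sidecar


def stage_mr(cfg: RunConfig) -> dict:
    names = _metabolite_names(cfg)
    os.makedirs(cfg.path("mr"), exist_ok=True)
    rows = []
    for name in names:
        for t in range(cfg.mr_n_traits):
            path = _require(cfg.path("mr_truth",
                                     f"{name}_trait_{t + 1:02d}.tsv"), "simulate")
            df = pd.read_csv(path, sep="\t")
            exposure = df.rename(columns={"beta_exposure": "beta",
                                          "se_exposure": "se"})[
                ["variant_id", "beta", "se", "effect_allele", "other_allele"]]
            outcome = df.rename(columns={"beta_outcome": "beta",
                                         "se_outcome": "se"})[
                ["variant_id", "beta", "se", "effect_allele", "other_allele"]]
            inst = mr.harmonize(exposure, outcome)
            est = mr.ivw_estimate(inst)
            rows.append({"metabolite": name, "trait": f"trait_{t + 1:02d}",
                         "theta": est.theta_hat, "se": est.se, "p": est.p,
                         "n_instruments": est.n_instruments})
    estimates = mr.filter_large_effects(pd.DataFrame(rows),
                                        cfg.mr_filter_threshold)
    estimates.to_csv(cfg.path("mr", "estimates.tsv"), sep="\t", index=False)
    scores = mr.importance_scores(estimates)
    scores.rename_axis("metabolite").reset_index().to_csv(
        cfg.path("mr", "importance.tsv"), sep="\t", index=False)
    n_filtered = int(estimates["filtered"].sum())
    log.info("mr: %d estimates, %d filtered as overlap", len(estimates),
             n_filtered)
    return {"n_estimates": len(estimates), "n_filtered": n_filtered}


def stage_conserve(cfg: RunConfig, organs_subset: list[str] | None = None) -> dict:
    tree = cons.read_tree(_require(cfg.path("tree.nwk"), "simulate"))
    per_organ: dict[str, pd.Series] = {}
    rates: dict[str, pd.Series] = {}
    for organ in cfg.organ_list:
        mat = cons.read_concentrations(
            _require(cfg.path("concentrations", f"{organ}.tsv"), "simulate"))
        mat = mat.dropna(how="all")
        table = cons.conservation_scores(tree, mat)
        per_organ[organ] = table["score"]
        rates[organ] = table["sigma2"]
    agg = cons.aggregate_conservation(per_organ, organs_subset)
    os.makedirs(cfg.path("conserve"), exist_ok=True)
    out = agg.copy()
    for organ in cfg.organ_list:
        out[f"sigma2_{organ}"] = rates[organ]
        out[f"score_{organ}"] = per_organ[organ]
    out.rename_axis("metabolite").to_csv(cfg.path("conserve", "conservation.tsv"),
                                         sep="\t")
    log.info("conserve: aggregated %d metabolites over %d organs", len(agg),
             len(organs_subset or cfg.organ_list))
    return {"n_metabolites": len(agg)}


def stage_stats(cfg: RunConfig) -> dict:
    report = pd.read_csv(_require(cfg.path("alpha", "alpha_report.tsv"),
                                  "alpha"), sep="\t")
    sigma_full, sig_labels = gencorr.read_matrix(
        _require(cfg.path("gencorr", "corr.tsv"), "gencorr"))
    conservation = pd.read_csv(_require(cfg.path("conserve", "conservation.tsv"),
                                        "conserve"), sep="\t",
                               index_col="metabolite")
    importance = pd.read_csv(_require(cfg.path("mr", "importance.tsv"), "mr"),
                             sep="\t", index_col="metabolite")["importance"]
    estimates = pd.read_csv(_require(cfg.path("mr", "estimates.tsv"), "mr"),
                            sep="\t")
    classes_df = pd.read_csv(_require(cfg.path("classes.tsv"), "simulate"),
                             sep="\t", index_col="metabolite")

    stable = report[report["stable"]].set_index("metabolite")
    results = []

    def sigma_for(mets: list[str]) -> np.ndarray:
        idx = [sig_labels.index(m) for m in mets]
        sub = sigma_full[np.ix_(idx, idx)]
        # repair the hair-negative eigenvalues file rounding can introduce
        return gencorr.CorrelationContext.from_estimate(sub, mets).sigma

    # alpha vs cross-species conservation (median rank)
    joint = stable.join(conservation["aggregate_median_rank"], how="inner")
    slope_cons = None
    if len(joint) >= 3:
        slope_cons = corrstats.adjusted_slope(
            joint["aggregate_median_rank"].to_numpy(),
            joint["alpha_hat"].to_numpy(), sigma_for(list(joint.index)))
        results.append({"test": "alpha_vs_conservation",
                        "statistic": slope_cons.r_hat, "df": slope_cons.n - 1,
                        "p": slope_cons.p})

    # alpha vs MR importance
    joint_imp = stable.join(importance, how="inner")
    if len(joint_imp) >= 3:
        slope_imp = corrstats.adjusted_slope(
            joint_imp["importance"].to_numpy(),
            joint_imp["alpha_hat"].to_numpy(), sigma_for(list(joint_imp.index)))
        results.append({"test": "alpha_vs_importance",
                        "statistic": slope_imp.r_hat, "df": slope_imp.n - 1,
                        "p": slope_imp.p})

    # per-trait slopes of |theta| on alpha, BH-flagged
    slope_rows = []
    filt = estimates[~estimates["filtered"]]
    for trait, grp in filt.groupby("trait"):
        grp = grp.set_index("metabolite").join(stable["alpha_hat"], how="inner")
        if len(grp) < 3:
            continue
        res = corrstats.adjusted_slope(grp["theta"].abs().to_numpy(),
                                       grp["alpha_hat"].to_numpy(),
                                       sigma_for(list(grp.index)))
        slope_rows.append({"trait": trait, "r": res.r_hat, "se": res.se,
                           "p": res.p, "n": res.n})
    slopes = pd.DataFrame(slope_rows)
    if len(slopes):
        slopes["bh_significant"] = corrstats.benjamini_hochberg(
            slopes["p"].to_numpy(), cfg.fdr)

    # heterogeneity of alpha across classes + class-vs-rest contrasts
    q_res = None
    if len(stable) >= 4:
        cls = corrstats.ClassAssignment(classes_df.loc[stable.index, "class"])
        if cls.k >= 2:
            sig = gencorr.CorrelationContext(
                sigma_for(list(stable.index)), labels=list(stable.index))
            q_res = corrstats.modified_cochran_q(
                stable["alpha_hat"].to_numpy(), stable["se"].to_numpy(),
                sig, cls)
            results.append({"test": "class_heterogeneity_Q",
                            "statistic": q_res.q, "df": q_res.df, "p": q_res.p})
            for c in cls.classes:
                t, p = corrstats.class_vs_rest(stable["alpha_hat"].to_numpy(),
                                               stable["se"].to_numpy(), sig,
                                               cls, c)
                results.append({"test": f"class_vs_rest[{c}]", "statistic": t,
                                "df": 1, "p": p})

    os.makedirs(cfg.path("stats"), exist_ok=True)
    pd.DataFrame(results).to_csv(cfg.path("stats", "results.tsv"), sep="\t",
                                 index=False)
    if len(slopes):
        slopes.to_csv(cfg.path("stats", "slopes.tsv"), sep="\t", index=False)
    summary = {
        "seed": cfg.seed,
        "n_metabolites": int(len(report)),
        "n_stable": int(len(stable)),
        "alpha_vs_conservation_slope": None if slope_cons is None
        else slope_cons.r_hat,
        "alpha_vs_conservation_p": None if slope_cons is None else slope_cons.p,
        "Q": None if q_res is None else q_res.q,
        "Q_p": None if q_res is None else q_res.p,
        "n_traits_negative_slope": int((slopes["r"] < 0).sum()) if len(slopes)
        else 0,
        "n_traits_bh_significant": int(slopes["bh_significant"].sum())
        if len(slopes) else 0,
    }
    with open(cfg.path("stats", "report.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary


_STAGE_FN = {"simulate": stage_simulate, "alpha": stage_alpha,
             "gencorr": stage_gencorr, "mr": stage_mr,
             "conserve": stage_conserve, "stats": stage_stats}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order; return the report."""
    cfg.validate()
    if stages is None:
        stages = STAGES if cfg.stages in ("all", "") else \
            [s.strip() for s in cfg.stages.split(",")]
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGES}")
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"seed": cfg.seed, "stages": stages}
    for s in sorted(stages, key=STAGES.index):
        log.info("running stage %s", s)
        report[s] = _STAGE_FN[s](cfg)
    with open(cfg.path("run_report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    return report
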