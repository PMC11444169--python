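"""Generative models: effect-size architectures, marginal statistics, MR and
Brownian-motion data with known ground truth."""

import numpy as np
import pytest

import metabsel as ms


# ---------------------------------------------------------------------------
# alpha-architecture effects
# ---------------------------------------------------------------------------

def test_zero_heritability_gives_all_zero_effects(nold_panel):
    spec = ms.ArchitectureSpec(h2=0.0, alpha=-0.5, n_samples=1000, seed=1)
    assert not np.any(ms.simulate_effects_alpha(nold_panel, spec))


def test_causal_subset_size_matches_prop_causal(nold_panel):
    spec = ms.ArchitectureSpec(h2=0.3, alpha=0.0, n_samples=1000,
                               prop_causal=0.25, seed=2)
    b = ms.simulate_effects_alpha(nold_panel, spec)
    assert np.count_nonzero(b) == round(0.25 * nold_panel.n_snps)


def test_realized_heritability_conserved_across_replicates(nold_panel):
    # mean realized h2 over replicates matches spec h2 within 3 MC SEs
    spec_h2 = 0.4
    vals = []
    for r in range(100):
        spec = ms.ArchitectureSpec(h2=spec_h2, alpha=-0.5, n_samples=1000,
                                   seed=100 + r)
        vals.append(ms.realized_h2(nold_panel,
                                   ms.simulate_effects_alpha(nold_panel, spec)))
    vals = np.asarray(vals)
    mc_se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean() - spec_h2) < 3 * mc_se


def test_alpha_minus_one_equalizes_heritability_contributions(nold_panel):
    # at alpha = -1 with unit weights every causal SNP has the same
    # expected contribution b^2 * 2f(1-f); check variances are 1/het
    spec = ms.ArchitectureSpec(h2=0.5, alpha=-1.0, n_samples=1000, seed=3)
    b = ms.simulate_effects_alpha(nold_panel, spec)
    q = b ** 2 * nold_panel.heterozygosity
    # expected contribution is flat: correlation of q with MAF should vanish
    r = np.corrcoef(q, nold_panel.maf)[0, 1]
    assert abs(r) < 0.05


def test_log_effect_variance_scales_with_alpha():
    # regress log mean(b^2) on log 2f(1-f) over MAF bins: slope ~ alpha
    alpha = -0.5
    panel = ms.simulate_panel(50_000, 50_000, 0.01, 0.5, 0.0, seed=11)
    spec = ms.ArchitectureSpec(h2=0.5, alpha=alpha, n_samples=1000, seed=12)
    b = ms.simulate_effects_alpha(panel, spec)
    het = panel.heterozygosity
    bins = np.quantile(het, np.linspace(0, 1, 21))
    idx = np.clip(np.digitize(het, bins) - 1, 0, 19)
    logm = np.array([np.log(np.mean(b[idx == k] ** 2)) for k in range(20)])
    logh = np.array([np.log(np.mean(het[idx == k])) for k in range(20)])
    slope = np.polyfit(logh, logm, 1)[0]
    assert abs(slope - alpha) < 0.1


# ---------------------------------------------------------------------------
# Eyre-Walker coupling
# ---------------------------------------------------------------------------

def test_eyre_walker_strong_limit_equalizes_per_snp_heritability(nold_panel):
    spec = ms.EyreWalkerSpec.strong_selection_limit(seed=4)
    panel2, b = ms.simulate_effects_eyre_walker(nold_panel, spec)
    q = b ** 2 * panel2.heterozygosity
    assert q.std() / q.mean() < 1e-8  # exactly frequency-independent


def test_eyre_walker_decoupled_limit_is_frequency_independent(nold_panel):
    # tau = 0 and no MAF coupling: effects carry no frequency signal
    spec = ms.EyreWalkerSpec(tau=0.0, maf_coupling=0.0, noise_sd=0.0, seed=5)
    panel2, b = ms.simulate_effects_eyre_walker(nold_panel, spec)
    r = np.corrcoef(b ** 2, panel2.heterozygosity)[0, 1]
    assert abs(r) < 0.08


def test_eyre_walker_deterministic_under_seed(nold_panel):
    spec = ms.EyreWalkerSpec(tau=0.5, maf_coupling=2.0, noise_sd=0.1, seed=6)
    p1, b1 = ms.simulate_effects_eyre_walker(nold_panel, spec)
    p2, b2 = ms.simulate_effects_eyre_walker(nold_panel, spec)
    assert np.array_equal(b1, b2)
    assert np.array_equal(p1.maf, p2.maf)


def test_eyre_walker_spec_validation():
    with pytest.raises(ValueError):
        ms.EyreWalkerSpec(tau=-0.1)
    with pytest.raises(ValueError):
        ms.EyreWalkerSpec(s_shape=0.0)


# ---------------------------------------------------------------------------
# marginal summary statistics
# ---------------------------------------------------------------------------

def test_null_chisq_mean_is_one(nold_panel):
    st = ms.simulate_sumstats(nold_panel, np.zeros(nold_panel.n_snps), 10_000,
                              seed=7)
    # central chi2_1: mean 1, var 2
    se = np.sqrt(2.0 / nold_panel.n_snps)
    assert abs(st.chisq.mean() - 1.0) < 4 * se


def test_noncentral_chisq_mean_matches_per_snp_heritability():
    # single causal SNP with per-SNP heritability q: E[S] = 1 + n q
    panel = ms.simulate_panel(10, 10, 0.1, 0.4, 0.0, seed=8)
    q, n = 1e-3, 10_000
    b = np.zeros(10)
    b[0] = np.sqrt(q / panel.heterozygosity[0])
    vals = [ms.simulate_sumstats(panel, b, n, seed=1000 + r).chisq[0]
            for r in range(1000)]
    expect = 1 + n * q
    # var of noncentral chi2: 2 + 4 n q
    mc_se = np.sqrt((2 + 4 * n * q) / 1000)
    assert abs(np.mean(vals) - expect) < 4 * mc_se


def test_perfect_ld_spreads_association_to_null_snp():
    # a null SNP in r=1 LD with a causal SNP has the same expected chi-square
    maf = np.array([0.3, 0.3])
    R = np.array([[1.0, 1.0], [1.0, 1.0]])
    panel = ms.SNPPanel(variant_id=np.array(["a", "b"], dtype=object), maf=maf,
                        block_id=np.array([0, 0]), ld_block_corr={0: R},
                        ld_score=np.array([2.0, 2.0]),
                        snp_weight=np.array([0.5, 0.5]))
    b = np.array([0.05, 0.0])
    chis = np.array([ms.simulate_sumstats(panel, b, 5000, seed=r).chisq
                     for r in range(500)])
    m1, m2 = chis.mean(axis=0)
    pooled_se = chis.std(axis=0).max() / np.sqrt(500)
    assert abs(m1 - m2) < 4 * pooled_se


def test_sumstats_validation_errors(nold_panel):
    with pytest.raises(ValueError):
        ms.simulate_sumstats(nold_panel, np.zeros(nold_panel.n_snps), 0, seed=0)
    with pytest.raises(ValueError):
        ms.simulate_sumstats(nold_panel, np.zeros(3), 100, seed=0)


# ---------------------------------------------------------------------------
# metabolite sets
# ---------------------------------------------------------------------------

def test_metabolite_set_requires_psd_sigma(nold_panel):
    G = np.array([[1.0, 1.2], [1.2, 1.0]])  # not PSD
    archs = [ms.ArchitectureSpec(h2=0.3, alpha=0.0, n_samples=1000, seed=1)
             for _ in range(2)]
    with pytest.raises(ValueError, match="semidefinite"):
        ms.MetabolitePanelSpec(2, G, archs)


def test_metabolite_set_alpha_ordering_recovered():
    # two traits at alpha = -1 and 0: fitted ordering preserved
    panel = ms.simulate_panel(4000, 4000, 0.01, 0.5, 0.0, seed=21)
    archs = [ms.ArchitectureSpec(h2=0.5, alpha=a, n_samples=50_000, seed=22)
             for a in (-1.0, 0.0)]
    spec = ms.MetabolitePanelSpec(2, np.eye(2), archs)
    stats, true_alpha, _ = ms.simulate_metabolite_set(spec, panel)
    fits = [ms.profile_alpha(s, panel) for s in stats]
    assert fits[0].alpha_hat < fits[1].alpha_hat
    assert abs(fits[0].alpha_hat - -1.0) < 0.3
    assert abs(fits[1].alpha_hat - 0.0) < 0.3


# ---------------------------------------------------------------------------
# MR datasets
# ---------------------------------------------------------------------------

def test_mr_noiseless_limit_recovers_theta_exactly():
    ds = ms.simulate_mr_dataset(20, theta=0.3, exposure_h2_per_instr=0.01,
                                n_exp=10 ** 12, n_out=10 ** 12,
                                pleiotropy_sd=0.0, seed=9)
    inst = ms.InstrumentSet(ds.variant_id, ds.beta_exposure, ds.se_exposure,
                            ds.beta_outcome, ds.se_outcome, ds.effect_allele,
                            ds.other_allele)
    est = ms.ivw_estimate(inst)
    assert abs(est.theta_hat - 0.3) < 1e-4


def test_mr_dataset_deterministic_and_validated():
    a = ms.simulate_mr_dataset(10, 0.2, seed=13)
    b = ms.simulate_mr_dataset(10, 0.2, seed=13)
    assert np.array_equal(a.beta_exposure, b.beta_exposure)
    assert np.array_equal(a.beta_outcome, b.beta_outcome)
    with pytest.raises(ValueError):
        ms.simulate_mr_dataset(0, 0.2, seed=1)


# ---------------------------------------------------------------------------
# Brownian motion on trees
# ---------------------------------------------------------------------------

def test_bm_zero_rate_gives_constant_tips(tree26):
    tips = ms.simulate_bm_traits(tree26, 0.0, root_value=3.5, seed=1)
    assert np.allclose(tips.to_numpy(), 3.5)


def test_bm_star_tree_tip_variance_matches_rate(star_tree):
    # star tree with unit branches: tips iid N(root, rate)
    draws = np.stack([ms.simulate_bm_traits(star_tree, 2.0, seed=r).to_numpy()
                      for r in range(2000)])
    var = draws.var(axis=0, ddof=1).mean()
    # var of sample variance of N(0,2) over 2000 draws, 30 tips averaged
    assert abs(var - 2.0) < 0.05


def test_bm_requires_positive_branch_lengths():
    import dendropy

    bad = dendropy.Tree.get(data="(A:1,B:0,C:1);", schema="newick")
    with pytest.raises(ValueError, match="positive branch lengths"):
        ms.simulate_bm_traits(bad, 1.0, seed=0)


def test_generators_are_seed_deterministic(nold_panel, tree26):
    spec = ms.ArchitectureSpec(h2=0.4, alpha=-0.3, n_samples=1000, seed=17)
    assert np.array_equal(ms.simulate_effects_alpha(nold_panel, spec),
                          ms.simulate_effects_alpha(nold_panel, spec))
    e = np.zeros(nold_panel.n_snps)
    assert np.array_equal(ms.simulate_sumstats(nold_panel, e, 100, seed=3).z,
                          ms.simulate_sumstats(nold_panel, e, 100, seed=3).z)
    assert ms.simulate_bm_traits(tree26, 1.0, seed=4).equals(
        ms.simulate_bm_traits(tree26, 1.0, seed=4))
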