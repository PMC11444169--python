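"""Heritability-model expectations, quasi-likelihood and the alpha profile fit."""

import numpy as np
import pytest

import metabsel as ms
from metabsel.alpha import AlphaFit, quadratic_vertex


def _panel_two_snps(mafs=(0.5, 0.1)):
    n = len(mafs)
    return ms.SNPPanel(
        variant_id=np.array([f"s{i}" for i in range(n)], dtype=object),
        maf=np.array(mafs), block_id=np.arange(n),
        ld_block_corr={i: np.array([[1.0]]) for i in range(n)},
        ld_score=np.ones(n), snp_weight=np.ones(n))


# ---------------------------------------------------------------------------
# expected per-SNP heritability and expected chi-square
# ---------------------------------------------------------------------------

def test_per_snp_h2_hand_normalization():
    # alpha = 0, unit weights, f = 0.5 and 0.1, h2 = 1:
    # shares are (0.5, 0.18) / 0.68
    panel = _panel_two_snps()
    model = ms.HeritabilityModel(h2=1.0, alpha=0.0)
    eh2 = ms.expected_per_snp_h2(panel, model)
    assert np.allclose(eh2, [0.5 / 0.68, 0.18 / 0.68], atol=1e-10)


def test_per_snp_h2_flat_at_alpha_minus_one(nold_panel):
    model = ms.HeritabilityModel(h2=0.5, alpha=-1.0)
    eh2 = ms.expected_per_snp_h2(nold_panel, model)
    assert np.allclose(eh2, 0.5 / nold_panel.n_snps)


@pytest.mark.parametrize("alpha", [-1.5, -1.0, -0.25, 0.0, 0.8])
def test_per_snp_h2_sums_to_h2_exactly(ld_panel, alpha):
    model = ms.HeritabilityModel(h2=0.37, alpha=alpha)
    assert np.isclose(ms.expected_per_snp_h2(ld_panel, model).sum(), 0.37,
                      atol=1e-12)


def test_stratified_per_snp_h2_sums_per_annotation(nold_panel):
    rng = np.random.default_rng(1)
    ann = rng.uniform(0.0, 1.0, size=(nold_panel.n_snps, 2))
    panel = ms.SNPPanel(variant_id=nold_panel.variant_id, maf=nold_panel.maf,
                        block_id=nold_panel.block_id,
                        ld_block_corr=nold_panel.ld_block_corr,
                        ld_score=nold_panel.ld_score,
                        snp_weight=nold_panel.snp_weight, annotations=ann)
    model = ms.HeritabilityModel(h2=0.5, alpha=-0.5,
                                 stratum_h2=np.array([0.2, 0.3]))
    eh2 = ms.expected_per_snp_h2(panel, model)
    assert np.isclose(eh2.sum(), 0.5, atol=1e-12)
    with pytest.raises(ValueError, match="sum to h2"):
        ms.HeritabilityModel(h2=0.5, alpha=0.0, stratum_h2=np.array([0.2, 0.2]))


def test_expected_chisq_null_model_is_one(ld_panel):
    model = ms.HeritabilityModel(h2=0.0, alpha=-0.25)
    assert np.allclose(ms.expected_chisq(ld_panel, model, 10_000), 1.0)


def test_expected_chisq_single_snp_by_hand():
    # one SNP with E[h2_j] = 1e-4 at n = 10,000: e = 1 + 1 = 2
    panel = _panel_two_snps((0.3,))
    model = ms.HeritabilityModel(h2=1e-4, alpha=-1.0)  # single SNP takes all
    e = ms.expected_chisq(panel, model, 10_000)
    assert np.isclose(e[0], 2.0, atol=1e-10)


def test_expected_chisq_perfect_ld_equalizes():
    R = np.ones((2, 2))
    panel = ms.SNPPanel(variant_id=np.array(["a", "b"], dtype=object),
                        maf=np.array([0.3, 0.3]), block_id=np.array([0, 0]),
                        ld_block_corr={0: R}, ld_score=np.array([2.0, 2.0]),
                        snp_weight=np.array([0.5, 0.5]))
    model = ms.HeritabilityModel(h2=2e-4, alpha=-1.0)
    e = ms.expected_chisq(panel, model, 10_000)
    assert np.isclose(e[0], e[1], atol=1e-12)


@pytest.mark.parametrize("alpha,h2", [(-1.8, 0.9), (-1.0, 0.5), (0.5, 0.1)])
def test_expected_chisq_at_least_one(ld_panel, alpha, h2):
    model = ms.HeritabilityModel(h2=h2, alpha=alpha)
    assert np.all(ms.expected_chisq(ld_panel, model, 50_000) >= 1.0)


# ---------------------------------------------------------------------------
# quasi-likelihood
# ---------------------------------------------------------------------------

def test_loglik_closed_form_at_null():
    # S = 1, e = 1, unit weights: each term is -log(2 pi)/2 - 1/2
    m = 50
    panel = ms.simulate_panel(m, m, 0.1, 0.4, 0.0, seed=1)
    stats = ms.SummaryStats(variant_id=panel.variant_id, chisq=np.ones(m),
                            n=np.full(m, 1000.0))
    model = ms.HeritabilityModel(h2=0.0, alpha=0.0)
    expect = m * (-0.5 * np.log(2 * np.pi) - 0.5)
    assert np.isclose(ms.model_loglik(stats, panel, model), expect, atol=1e-9)


def test_loglik_prefers_inflated_expectations_for_inflated_stats():
    m = 100
    panel = ms.simulate_panel(m, m, 0.1, 0.4, 0.0, seed=2)
    stats = ms.SummaryStats(variant_id=panel.variant_id,
                            chisq=np.full(m, 25.0), n=np.full(m, 50_000.0))
    low = ms.model_loglik(stats, panel, ms.HeritabilityModel(h2=0.0, alpha=0.0))
    hi = ms.model_loglik(stats, panel, ms.HeritabilityModel(h2=0.5, alpha=0.0))
    assert hi > low


def test_loglik_handles_zero_statistics():
    m = 10
    panel = ms.simulate_panel(m, m, 0.1, 0.4, 0.0, seed=3)
    stats = ms.SummaryStats(variant_id=panel.variant_id, chisq=np.zeros(m),
                            n=np.full(m, 1000.0))
    ll = ms.model_loglik(stats, panel, ms.HeritabilityModel(h2=0.1, alpha=0.0))
    assert np.isfinite(ll)


# ---------------------------------------------------------------------------
# h2 profiling
# ---------------------------------------------------------------------------

def test_h2_boundary_at_deflated_statistics():
    m = 500
    panel = ms.simulate_panel(m, m, 0.1, 0.4, 0.0, seed=4)
    stats = ms.SummaryStats(variant_id=panel.variant_id,
                            chisq=np.full(m, 0.5), n=np.full(m, 50_000.0))
    h2, ll, ok = ms.fit_h2_given_alpha(stats, panel, -0.25)
    assert h2 == 0.0
    model0 = ms.HeritabilityModel(h2=0.0, alpha=-0.25)
    assert ll >= ms.model_loglik(stats, panel, model0) - 1e-9


def test_h2_recovery_on_simulated_data():
    panel = ms.simulate_panel(20_000, 20_000, 0.01, 0.5, 0.0, seed=5)
    spec = ms.ArchitectureSpec(h2=0.3, alpha=-0.25, n_samples=50_000, seed=6)
    b = ms.simulate_effects_alpha(panel, spec)
    st = ms.simulate_sumstats(panel, b, 50_000, seed=7)
    h2, ll, ok = ms.fit_h2_given_alpha(st, panel, -0.25)
    assert ok
    assert abs(h2 - 0.3) < 0.05
    model0 = ms.HeritabilityModel(h2=0.0, alpha=-0.25)
    assert ll >= ms.model_loglik(st, panel, model0)


# ---------------------------------------------------------------------------
# quadratic vertex and profile fit
# ---------------------------------------------------------------------------

def test_quadratic_vertex_closed_form():
    grid = np.linspace(-1, 0.5, 31)
    vals = -((grid + 0.5) ** 2)
    coeffs, ah, se, r2 = quadratic_vertex(grid, vals)
    assert abs(ah - (-0.5)) < 1e-10
    assert abs(se - np.sqrt(0.5)) < 1e-10
    assert r2 > 1 - 1e-12


@pytest.mark.parametrize("a,b,c", [(-3.0, 1.2, 0.5), (-0.5, -0.7, 2.0),
                                   (-10.0, 0.0, -1.0)])
def test_quadratic_vertex_recovers_arbitrary_concave_quadratics(a, b, c):
    grid = np.linspace(-2, 2, 17)
    vals = a * grid ** 2 + b * grid + c
    _, ah, se, _ = quadratic_vertex(grid, vals)
    assert abs(ah - (-b / (2 * a))) < 1e-10
    assert abs(se - np.sqrt(1 / (-2 * a))) < 1e-10


def test_quadratic_vertex_convex_input_withheld():
    grid = np.linspace(-1, 1, 11)
    _, ah, se, _ = quadratic_vertex(grid, grid ** 2)
    assert np.isnan(ah) and np.isnan(se)


def test_default_profile_grid_has_31_points():
    panel = ms.simulate_panel(3000, 3000, 0.01, 0.5, 0.0, seed=8)
    spec = ms.ArchitectureSpec(h2=0.5, alpha=-0.3, n_samples=50_000, seed=9)
    b = ms.simulate_effects_alpha(panel, spec)
    st = ms.simulate_sumstats(panel, b, 50_000, seed=10)
    fit = ms.profile_alpha(st, panel)
    if fit.range_used == (-1.0, 0.5):  # no extension triggered
        assert len(fit.grid) == 31
        assert fit.grid[0] == -1.0 and fit.grid[-1] == 0.5
    assert np.allclose(np.diff(fit.grid), 0.05)
    assert fit.stable
    assert abs(fit.alpha_hat - (-0.3)) < 3 * fit.se_alpha


def test_profile_extends_range_for_boundary_alpha():
    # truth at the default left boundary: range must extend to [-2, 1]
    panel = ms.simulate_panel(4000, 4000, 0.01, 0.5, 0.0, seed=11)
    spec = ms.ArchitectureSpec(h2=0.5, alpha=-1.0, n_samples=50_000, seed=12)
    b = ms.simulate_effects_alpha(panel, spec)
    st = ms.simulate_sumstats(panel, b, 50_000, seed=13)
    fit = ms.profile_alpha(st, panel)
    assert fit.range_used == (-2.0, 1.0)
    assert fit.stable
    assert abs(fit.alpha_hat - (-1.0)) < 0.15


def test_se_decreases_with_sample_size():
    panel = ms.simulate_panel(8000, 8000, 0.01, 0.5, 0.0, seed=14)
    ses = {}
    for n in (10_000, 100_000):
        spec = ms.ArchitectureSpec(h2=0.5, alpha=-0.25, n_samples=n, seed=15)
        b = ms.simulate_effects_alpha(panel, spec)
        st = ms.simulate_sumstats(panel, b, n, seed=16)
        ses[n] = ms.profile_alpha(st, panel).se_alpha
    assert ses[100_000] < ses[10_000]


def test_profile_rejects_bad_grid():
    panel = ms.simulate_panel(10, 10, 0.1, 0.4, 0.0, seed=0)
    stats = ms.SummaryStats(variant_id=panel.variant_id, chisq=np.ones(10),
                            n=np.full(10, 100.0))
    with pytest.raises(ValueError):
        ms.profile_alpha(stats, panel, grid_lo=0.5, grid_hi=-1.0)
    with pytest.raises(ValueError):
        ms.profile_alpha(stats, panel, step=0.0)


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def _fit(alpha_hat, se):
    return AlphaFit(grid=np.linspace(-1, 0.5, 31), loglik=np.zeros(31),
                    quad_coeffs=(-1.0, 0.0, 0.0), alpha_hat=alpha_hat,
                    se_alpha=se, h2_at_hat=0.3, range_used=(-1.0, 0.5),
                    stable=True, p_value=np.nan, r_squared=1.0)


def test_wald_test_hand_example():
    z, p, nom, bon = ms.wald_selection_test(_fit(-1.37, 0.5), n_tests=97)
    assert np.isclose(z, -2.74)
    assert abs(p - 0.0061) < 2e-4
    assert nom and not bon  # 0.05/97 ~ 5.15e-4


def test_wald_test_null_and_single_test():
    z, p, nom, bon = ms.wald_selection_test(_fit(0.0, 0.5))
    assert p == 1.0 and not nom and not bon
    z, p, nom, bon = ms.wald_selection_test(_fit(-1.0, 0.4), n_tests=1)
    assert nom == bon


def test_wald_test_requires_stable_fit():
    fit = _fit(-1.0, 0.5)
    fit.stable = False
    with pytest.raises(ValueError, match="stable"):
        ms.wald_selection_test(fit)
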