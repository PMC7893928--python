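"""Point-normal shrinkage: closed forms, Gibbs-vs-analytic equivalences,
aggregate heritability estimation."""
import numpy as np
import pytest
from scipy import integrate, stats

from conftest import make_panel, make_sumstats
from lipidprs.shrink import (LdMatrixWindowed, RHO_GRID, ShrinkConfig,
                             build_ld_windows, estimate_h2_aggregate,
                             grid_candidates_bayes, shrink_gibbs, shrink_inf)


def _identity_ld(m, radius=2):
    corr = np.zeros((m, 2 * radius + 1))
    corr[:, radius] = 1.0
    return LdMatrixWindowed(radius, corr)


def _cfg(**kw):
    base = dict(rho=1.0, h2=0.5, n_gwas=10_000, m=100, ld_radius=2,
                n_iter=120, burn_in=20, seed=5)
    base.update(kw)
    return ShrinkConfig(**base)


# ---------------------------------------------------------------------------
# LD windows

def test_ld_windows_basics(rng):
    x = rng.binomial(2, 0.4, (200, 1)).astype(float)
    dup = np.column_stack([x, x, rng.binomial(2, 0.4, (200, 1))])
    panel = make_panel(dup)
    ld = build_ld_windows(panel, 2)
    assert ld.r(0, 1) == pytest.approx(1.0, abs=1e-12)
    assert ld.r(0, 0) == 1.0
    for i in range(3):
        for j in range(3):
            assert ld.r(i, j) == pytest.approx(ld.r(j, i))
    ld0 = build_ld_windows(panel, 0)
    assert ld0.corr.shape == (3, 1)
    assert np.all(ld0.corr == 1.0)


def test_ld_windows_respect_chromosomes(rng):
    dos = rng.binomial(2, 0.4, (100, 4)).astype(float)
    panel = make_panel(dos, chrom=["1", "1", "2", "2"],
                       pos=[100, 200, 100, 200])
    ld = build_ld_windows(panel, 3)
    assert ld.r(1, 2) == 0.0  # across the chromosome boundary


def test_ld_windows_reject_monomorphic():
    panel = make_panel(np.column_stack([np.ones(50), np.arange(50) % 3]))
    with pytest.raises(ValueError, match="monomorphic"):
        build_ld_windows(panel, 1)


# ---------------------------------------------------------------------------
# infinitesimal closed form

def test_inf_identity_ld_scalar_shrinkage(rng):
    m, n, h2 = 100, 10_000, 0.5
    panel = make_panel(rng.binomial(2, 0.3, (50, m)).astype(float))
    beta = rng.normal(0, 0.05, m)
    ss = make_sumstats(panel, beta)
    ws = shrink_inf(ss, _identity_ld(m), _cfg(m=m, n_gwas=n, h2=h2))
    factor = 1.0 / (1.0 + m / (n * h2))
    np.testing.assert_allclose(ws.weights, factor * beta, rtol=1e-12)
    assert factor == pytest.approx(1 / 1.02)

    big = shrink_inf(ss, _identity_ld(m), _cfg(m=m, n_gwas=n, h2=1e6))
    assert np.max(np.abs(big.weights / beta - 1)) < 1e-4  # shrinkage -> 1

    zero = shrink_inf(make_sumstats(panel, np.zeros(m)), _identity_ld(m),
                      _cfg(m=m))
    assert np.all(zero.weights == 0)


def test_inf_matches_direct_solve_with_ld(rng):
    """Oracle: build D from np.corrcoef on the panel and solve directly."""
    m, n_ref = 24, 400
    base = rng.binomial(2, 0.4, (n_ref, m)).astype(float)
    for k in range(1, m):
        mix = rng.random(n_ref) < 0.5
        base[:, k] = np.where(mix, base[:, k - 1], base[:, k])
    panel = make_panel(base)
    beta = rng.normal(0, 0.05, m)
    ss = make_sumstats(panel, beta)
    cfg = _cfg(m=m, ld_radius=m)  # single solve window covers everything
    ld = build_ld_windows(panel, m)
    got = shrink_inf(ss, ld, cfg).weights
    d_oracle = np.corrcoef(base, rowvar=False)
    lam = cfg.m / (cfg.n_gwas * cfg.h2)
    expected = np.linalg.solve(d_oracle + lam * np.eye(m), beta)
    np.testing.assert_allclose(got, expected, atol=1e-10)


def test_inf_weights_shrink_with_h2(rng):
    m = 30
    panel = make_panel(rng.binomial(2, 0.3, (50, m)).astype(float))
    beta = rng.normal(0, 0.05, m)
    ss = make_sumstats(panel, beta)
    prev = np.abs(beta)
    for h2 in (0.8, 0.4, 0.1, 0.02):
        w = np.abs(shrink_inf(ss, _identity_ld(m), _cfg(m=m, h2=h2)).weights)
        assert np.all(w <= prev + 1e-15)
        prev = w


# ---------------------------------------------------------------------------
# Gibbs sampler

def posterior_mean_quadrature(beta_hat, n, rho, sigma2):
    """Numerical-integration oracle for the no-LD point-normal posterior."""
    tau = np.sqrt(1.0 / n)

    def joint(b):
        like = stats.norm.pdf(beta_hat, loc=b, scale=tau)
        prior = rho * stats.norm.pdf(b, scale=np.sqrt(sigma2))
        return like * prior

    lim = 10 * np.sqrt(sigma2)
    spike = [beta_hat - 8 * tau, beta_hat, beta_hat + 8 * tau]  # narrow
    num, _ = integrate.quad(lambda b: b * joint(b), -lim, lim,
                            points=spike, limit=200)
    den, _ = integrate.quad(joint, -lim, lim, points=spike, limit=200)
    den += (1 - rho) * stats.norm.pdf(beta_hat, scale=tau)
    return num / den


def _gibbs_replicates(ss, ld, cfg, n_seeds=10):
    runs = np.array([
        shrink_gibbs(ss, ld, ShrinkConfig(**{**cfg.__dict__,
                                             "seed": s})).weights
        for s in range(n_seeds)])
    return runs.mean(axis=0), runs.std(axis=0, ddof=1) / np.sqrt(n_seeds)


def test_gibbs_deterministic_given_seed(rng):
    m = 40
    panel = make_panel(rng.binomial(2, 0.3, (60, m)).astype(float))
    ss = make_sumstats(panel, rng.normal(0, 0.05, m))
    ld = _identity_ld(m)
    a = shrink_gibbs(ss, ld, _cfg(m=m, rho=0.1))
    b = shrink_gibbs(ss, ld, _cfg(m=m, rho=0.1))
    np.testing.assert_array_equal(a.weights, b.weights)


def test_gibbs_null_input_gives_null_weights(rng):
    m = 50
    panel = make_panel(rng.binomial(2, 0.3, (60, m)).astype(float))
    ss = make_sumstats(panel, np.zeros(m))
    mean, se = _gibbs_replicates(ss, _identity_ld(m), _cfg(m=m, rho=0.3))
    assert np.all(np.abs(mean) <= 3 * np.maximum(se, 1e-6))


def test_gibbs_rho1_matches_infinitesimal(rng):
    m, n_ref = 30, 500
    base = rng.binomial(2, 0.4, (n_ref, m)).astype(float)
    for k in range(1, m):
        mix = rng.random(n_ref) < 0.4
        base[:, k] = np.where(mix, base[:, k - 1], base[:, k])
    panel = make_panel(base)
    beta = rng.normal(0, 0.03, m)
    ss = make_sumstats(panel, beta)
    cfg = _cfg(m=m, ld_radius=m, rho=1.0, n_iter=300, burn_in=50)
    ld = build_ld_windows(panel, m)
    inf_w = shrink_inf(ss, ld, cfg).weights
    mean, se = _gibbs_replicates(ss, ld, cfg)
    assert np.all(np.abs(mean - inf_w) <= 3 * np.maximum(se, 1e-8))


def test_gibbs_identity_ld_matches_analytic_posterior(rng):
    m, n = 40, 10_000
    rho, h2 = 0.1, 0.5
    panel = make_panel(rng.binomial(2, 0.3, (60, m)).astype(float))
    beta = rng.normal(0, 0.02, m)
    ss = make_sumstats(panel, beta, n=n)
    cfg = _cfg(m=m, rho=rho, h2=h2, n_gwas=n, n_iter=400, burn_in=50)
    mean, se = _gibbs_replicates(ss, _identity_ld(m), cfg)
    sigma2 = h2 / (m * rho)
    expected = np.array([posterior_mean_quadrature(b, n, rho, sigma2)
                         for b in beta])
    assert np.all(np.abs(mean - expected) <= 3 * np.maximum(se, 1e-8))


def test_gibbs_divergence_detected(rng):
    # perfectly duplicated variants + an absurd prior variance: sampled
    # effects dwarf the near-zero marginals and trip the divergence guard
    col = rng.binomial(2, 0.3, (40, 1)).astype(float)
    panel = make_panel(np.repeat(col, 5, axis=1))
    ss = make_sumstats(panel, np.full(5, 1e-9))
    cfg = _cfg(m=1, rho=1.0, h2=0.99, n_gwas=10**9, ld_radius=2)
    with pytest.raises(RuntimeError, match="divergent"):
        shrink_gibbs(ss, build_ld_windows(panel, 2), cfg)


# ---------------------------------------------------------------------------
# aggregate h2 and the rho grid

def test_h2_null_hits_lower_clip():
    from lipidprs.sim import SimulationConfig, simulate_architecture, \
        simulate_gwas_summary, simulate_reference_panel
    cfg = SimulationConfig(n_ref=200, n_gwas=3000, m_variants=300,
                           block_size=1, h2=0.0, seed=3)
    panel = simulate_reference_panel(cfg)
    ss = simulate_gwas_summary(panel, simulate_architecture(cfg, panel), cfg)
    ld = build_ld_windows(panel, 5)
    assert estimate_h2_aggregate(ss, ld) == pytest.approx(0.01)


def test_h2_recovery_no_ld():
    from lipidprs.sim import SimulationConfig, simulate_architecture, \
        simulate_gwas_summary, simulate_reference_panel
    ests = []
    for seed in range(3):
        cfg = SimulationConfig(n_ref=300, n_gwas=20_000, m_variants=2000,
                               block_size=1, p_causal=0.05, h2=0.5, seed=seed)
        panel = simulate_reference_panel(cfg)
        arch = simulate_architecture(cfg, panel)
        ss = simulate_gwas_summary(panel, arch, cfg)
        ests.append(estimate_h2_aggregate(ss, build_ld_windows(panel, 10)))
    for est in ests:
        assert abs(est - 0.5) < 0.1


def test_rho_grid_candidates(rng):
    m = 60
    panel = make_panel(rng.binomial(2, 0.35, (80, m)).astype(float))
    ss = make_sumstats(panel, rng.normal(0, 0.05, m))
    cfg = _cfg(m=m, n_iter=40, burn_in=5)
    cands = grid_candidates_bayes(ss, panel, cfg)
    assert len(cands) == 7
    assert [ws.provenance["rho"] for ws in cands] == list(RHO_GRID)
    again = grid_candidates_bayes(ss, panel, cfg)
    for a, b in zip(cands, again):
        np.testing.assert_array_equal(a.weights, b.weights)


def test_rho_grid_allowlist_filters(rng):
    m = 20
    panel = make_panel(rng.binomial(2, 0.35, (60, m)).astype(float))
    ss = make_sumstats(panel, rng.normal(0, 0.05, m))
    allow = frozenset(panel.variants["id"].iloc[:12])
    cfg = _cfg(m=12, n_iter=30, burn_in=5, variant_allowlist=allow)
    cands = grid_candidates_bayes(ss, panel, cfg)
    assert all(len(ws) == 12 for ws in cands)
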