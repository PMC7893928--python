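"""Point-normal Bayesian shrinkage of GWAS effects given reference LD.

Re-weights marginal summary statistics under the mixture prior in which a
fraction rho of variants is causal with effects N(0, h2/(M*rho)) and the rest
are exactly zero, using windowed LD from a reference panel.  The rho -> 1
(infinitesimal) special case has the closed form (D + M/(N*h2) I) beta = beta_hat
per LD window; the general case is estimated by a Gibbs sampler whose reported
weight is the average per-iteration posterior-mean effect.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy import stats

from .io import GenotypePanel, SummaryStats, WeightSet

#: the rho tuning grid: assumed fractions of markers with non-zero effects
RHO_GRID = (1.0, 0.3, 0.1, 0.03, 0.01, 3e-3, 1e-3)


@dataclass(frozen=True)
class ShrinkConfig:
    rho: float
    h2: float
    n_gwas: int
    m: int
    ld_radius: int = 10
    n_iter: int = 100
    burn_in: int = 10
    seed: int = 0
    variant_allowlist: frozenset | None = None

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if not self.n_iter > self.burn_in >= 0:
            raise ValueError("need n_iter > burn_in >= 0")


def default_ld_radius(m: int) -> int:
    """Window half-width in variants: m/3000, floored at 10."""
    return max(10, m // 3000)


@dataclass
class LdMatrixWindowed:
    """Banded signed-correlation storage: ``corr[i, radius + d]`` holds
    r(variant i, variant i+d) for |d| <= radius, zero across chromosome
    boundaries and outside the array."""

    radius: int
    corr: np.ndarray  # (m, 2*radius + 1)

    def r(self, i: int, j: int) -> float:
        d = j - i
        if abs(d) > self.radius:
            return 0.0
        return float(self.corr[i, self.radius + d])


def build_ld_windows(panel: GenotypePanel, ld_radius: int) -> LdMatrixWindowed:
    """Signed Pearson correlations between each variant and its neighbors
    within ``ld_radius`` positions in the variant ordering (same chromosome
    only).  Monomorphic variants have undefined correlation and raise."""
    d = panel.dosages
    sd = np.nanstd(d, axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"monomorphic variant at index {bad}")
    z = (d - np.nanmean(d, axis=0)) / sd
    z = np.nan_to_num(z)  # missing contributes zero after centering
    m = panel.n_variants
    chrom = panel.variants["chrom"].to_numpy()
    corr = np.zeros((m, 2 * ld_radius + 1))
    corr[:, ld_radius] = 1.0
    n = d.shape[0]
    for off in range(1, ld_radius + 1):
        if off >= m:
            break
        r = (z[:, :-off] * z[:, off:]).sum(axis=0) / n
        same = chrom[:-off] == chrom[off:]
        r = np.where(same, r, 0.0)
        corr[:-off, ld_radius + off] = r
        corr[off:, ld_radius - off] = r
    return LdMatrixWindowed(ld_radius, corr)


def _band_to_dense(ld: LdMatrixWindowed, lo: int, hi: int) -> np.ndarray:
    """Materialize the correlation matrix of variants [lo, hi)."""
    k = hi - lo
    out = np.eye(k)
    for a in range(k):
        for b in range(a + 1, min(k, a + ld.radius + 1)):
            out[a, b] = out[b, a] = ld.corr[lo + a, ld.radius + (b - a)]
    return out


def _windows(m: int, radius: int):
    """Disjoint solve windows of width 2*radius (at least one)."""
    width = max(2 * radius, 1)
    for lo in range(0, m, width):
        yield lo, min(lo + width, m)


def shrink_inf(ss: SummaryStats, ld: LdMatrixWindowed,
               cfg: ShrinkConfig) -> WeightSet:
    """Infinitesimal-model posterior means: per disjoint LD window solve
    (D + M/(N*h2) I) w = beta_hat."""
    beta_hat = ss.table["beta"].to_numpy(float)
    m = len(beta_hat)
    lam = cfg.m / (cfg.n_gwas * cfg.h2)
    out = np.empty(m)
    for lo, hi in _windows(m, ld.radius):
        d_mat = _band_to_dense(ld, lo, hi)
        out[lo:hi] = np.linalg.solve(
            d_mat + lam * np.eye(hi - lo), beta_hat[lo:hi])
    return WeightSet(ss.table[["chrom", "pos", "id", "ea", "nea"]].copy(),
                     out, _prov(cfg, "bayes-inf", m))


@njit(cache=True)
def _gibbs_kernel(beta_hat, corr, radius, sigma2, tau2, rho,
                  n_iter, burn_in, seed):
    m = beta_hat.shape[0]
    np.random.seed(seed)
    cur = np.zeros(m)          # sampled effects
    acc = np.zeros(m)          # accumulated posterior means
    shrink = sigma2 / (sigma2 + tau2)
    var_post = tau2 * shrink
    sd_post = np.sqrt(var_post)
    # log-density constants for the causal-probability odds
    s_c = sigma2 + tau2
    for it in range(n_iter):
        for j in range(m):
            resid = beta_hat[j]
            lo = max(0, j - radius)
            hi = min(m, j + radius + 1)
            for k in range(lo, hi):
                if k != j:
                    resid -= corr[j, radius + (k - j)] * cur[k]
            # posterior odds of the causal component at residualized effect
            log_odds = (np.log(rho / (1.0 - rho)) if rho < 1.0 else np.inf)
            if rho < 1.0:
                log_odds += 0.5 * np.log(tau2 / s_c) \
                    + 0.5 * resid * resid * (1.0 / tau2 - 1.0 / s_c)
                p_causal = 1.0 / (1.0 + np.exp(-log_odds))
            else:
                p_causal = 1.0
            mean_c = shrink * resid
            if it >= burn_in:
                acc[j] += p_causal * mean_c
            if np.random.random() < p_causal:
                cur[j] = mean_c + sd_post * np.random.normal()
            else:
                cur[j] = 0.0
    return acc / (n_iter - burn_in)


def shrink_gibbs(ss: SummaryStats, ld: LdMatrixWindowed,
                 cfg: ShrinkConfig) -> WeightSet:
    """Point-normal Gibbs sampler over the windowed LD structure.

    Each sweep residualizes every marginal effect against the current sampled
    effects of its LD neighbors, forms the posterior causal probability and
    conditional mean/variance under the point-normal prior (causal variance
    h2/(M*rho), sampling variance 1/N), and samples.  Output weights average
    the per-iteration posterior means after burn-in.
    """
    beta_hat = ss.table["beta"].to_numpy(float)
    m = len(beta_hat)
    sigma2 = cfg.h2 / (cfg.m * cfg.rho)
    tau2 = 1.0 / cfg.n_gwas
    w = _gibbs_kernel(beta_hat, ld.corr, ld.radius, sigma2, tau2,
                      float(cfg.rho), cfg.n_iter, cfg.burn_in,
                      cfg.seed % (2**31))
    cap = 10.0 * np.max(np.abs(beta_hat)) if m else 0.0
    if m and np.max(np.abs(w)) > cap:
        raise RuntimeError(
            f"divergent Gibbs chain: max |weight| {np.max(np.abs(w)):.3g} "
            f"exceeds 10*max|beta_hat| = {cap:.3g}")
    return WeightSet(ss.table[["chrom", "pos", "id", "ea", "nea"]].copy(),
                     w, _prov(cfg, "bayes", m))


def posterior_mean_no_ld(beta_hat: float, n: int, rho: float,
                         sigma2: float) -> float:
    """Analytic point-normal posterior mean for a single variant with no LD:
    the mixing weight of the causal component times its conditional mean."""
    tau2 = 1.0 / n
    if rho >= 1.0:
        return sigma2 / (sigma2 + tau2) * beta_hat
    num = rho * stats.norm.pdf(beta_hat, scale=np.sqrt(sigma2 + tau2))
    den = num + (1 - rho) * stats.norm.pdf(beta_hat, scale=np.sqrt(tau2))
    return float(num / den * sigma2 / (sigma2 + tau2) * beta_hat)


def estimate_h2_aggregate(ss: SummaryStats, ld: LdMatrixWindowed) -> float:
    """Aggregate heritability from summary statistics and LD scores:
    h2 = M*(mean chi2 - 1)/(N * mean LD score), clipped to [0.01, 0.99].
    The LD score of a variant is the sum of r2 over its window (incl. itself).
    """
    df = ss.table
    if len(df) < 100:
        raise ValueError("need at least 100 variants to estimate h2")
    chi2 = (df["beta"] / df["se"]) ** 2
    ld_scores = (ld.corr ** 2).sum(axis=1)
    n = float(df["n"].mean())
    est = len(df) * (chi2.mean() - 1.0) / (n * ld_scores.mean())
    if chi2.mean() <= 1.0:
        import logging
        logging.getLogger(__name__).warning(
            "mean chi2 <= 1; h2 estimate clipped to lower bound")
    return float(np.clip(est, 0.01, 0.99))


def grid_candidates_bayes(ss: SummaryStats, panel: GenotypePanel,
                          base_cfg: ShrinkConfig) -> list[WeightSet]:
    """One shrunk weight set per rho in the default grid (7 candidates).

    Marginal effects are moved to the per-SD (standardized-genotype) scale
    using panel allele frequencies before shrinkage and moved back after, so
    the point-normal variance h2/(M*rho) applies on the scale the model
    assumes.  An optional variant-ID allow-list restricts the input first.
    """
    table = ss.table
    if base_cfg.variant_allowlist is not None:
        keep = table["id"].isin(base_cfg.variant_allowlist).to_numpy()
        table = table[keep].reset_index(drop=True)
    pos_key = {(c, p): k for k, (c, p) in
               enumerate(zip(panel.variants["chrom"], panel.variants["pos"]))}
    panel_idx = np.array([pos_key[(c, p)] for c, p in
                          zip(table["chrom"], table["pos"])])
    sub_panel = (panel if len(panel_idx) == panel.n_variants
                 and np.array_equal(panel_idx, np.arange(panel.n_variants))
                 else panel.subset_variants(panel_idx))

    eaf = sub_panel.eaf()
    sd_x = np.sqrt(np.maximum(2.0 * eaf * (1.0 - eaf), 1e-12))
    std = table.copy()
    std["beta"] = std["beta"].to_numpy() * sd_x
    ss_std = SummaryStats(std)
    ld = build_ld_windows(sub_panel, base_cfg.ld_radius)

    out = []
    for rho in RHO_GRID:
        cfg = replace(base_cfg, rho=rho)
        ws = shrink_gibbs(ss_std, ld, cfg)
        ws.weights = ws.weights / sd_x
        ws.provenance["n_variants"] = len(ws)
        out.append(ws)
    return out


def _prov(cfg: ShrinkConfig, method: str, n: int) -> dict:
    return {"method": method, "rho": cfg.rho, "h2": cfg.h2,
            "n_gwas": cfg.n_gwas, "m": cfg.m, "ld_radius": cfg.ld_radius,
            "n_iter": cfg.n_iter, "burn_in": cfg.burn_in, "seed": cfg.seed,
            "n_variants": n}
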