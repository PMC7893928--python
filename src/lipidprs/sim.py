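"""Synthetic genotype / GWAS / cohort generator with known ground truth.

Genotypes have blockwise LD: within each block of ``block_size`` variants a
latent Gaussian AR(1) process (lag-one correlation ``ld_decay``) is thresholded
per haplotype at the target allele frequency, giving Hardy-Weinberg genotype
classes and controllable within-block LD; blocks are independent.  Causal
architecture is point-normal: a fraction ``p_causal`` of variants receives a
Normal effect, scaled so the genetic variance over a panel equals ``h2`` on the
unit-variance latent ln-trait scale.  GWAS summary statistics are per-variant
marginal simple regressions on a fresh sample of size ``n_gwas``; cohorts are
further fresh draws with lipid phenotypes, covariates, and role-specific
outcomes (longitudinal follow-up, a cIMT-like measure, or CHD case status).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypePanel, SummaryStats

logger = logging.getLogger(__name__)

#: ln-scale intercepts (mmol/l geometric means) and latent SD of the traits
TRAIT_MU = {"tc": math.log(5.0), "tg": math.log(1.4),
            "hdl": math.log(1.35), "ldl": math.log(2.9)}
TRAIT_SD = 0.2

BLOCKS_PER_CHROM = 10
POS_SPACING = 10_000  # bp between adjacent variants
ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))

ROLES = ("validation", "testing", "reference-quintile", "longitudinal",
         "cimt", "chd")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_ref: int = 500
    n_gwas: int = 20_000
    m_variants: int = 2000
    block_size: int = 20
    ld_decay: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    p_causal: float = 0.01
    h2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_variants < 1 or self.n_ref < 2 or self.n_gwas < 3:
            raise ConfigurationError("non-positive/too-small dimensions")
        if not 0 <= self.ld_decay < 1:
            raise ConfigurationError("ld_decay must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not 0 < self.p_causal <= 1:
            raise ConfigurationError("p_causal must be in (0, 1]")
        if not 0 <= self.h2 < 1:
            raise ConfigurationError("h2 must be in [0, 1)")


@dataclass
class TrueArchitecture:
    causal_mask: np.ndarray
    beta_true: np.ndarray


@dataclass
class CohortSpec:
    label: str
    n: int
    role: str = "validation"
    covariate_effects: dict = field(default_factory=lambda: {
        "sex": 0.05, "age": 0.002, "bmi": 0.01})
    outcome_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown cohort role {self.role!r}")


@dataclass
class CohortTable:
    label: str
    role: str
    table: pd.DataFrame
    panel: GenotypePanel
    genetic_value: np.ndarray  # ground truth, for oracles only


# ---------------------------------------------------------------------------
# generative process shared between panel, GWAS sample, and cohorts

def _rng(config: SimulationConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed % (2**31), *tags]))


def _structure(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic variant metadata (freqs, map positions, alleles)."""
    rng = _rng(config, 1)
    m = config.m_variants
    freq = rng.uniform(*config.maf_range, size=m)
    block = np.arange(m) // config.block_size
    chrom = (block // BLOCKS_PER_CHROM + 1).astype(str)
    pos = np.empty(m, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = 1_000_000 + POS_SPACING * np.arange(len(idx))
    pairs = [ALLELE_PAIRS[i % len(ALLELE_PAIRS)] for i in range(m)]
    return pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "id": [f"rs{c}_{p}" for c, p in zip(chrom, pos)],
        "ea": [a for a, _ in pairs], "nea": [b for _, b in pairs],
        "freq": freq, "block": block,
    })


def _draw_genotypes(config: SimulationConfig, structure: pd.DataFrame,
                    n: int, rng: np.random.Generator) -> np.ndarray:
    """Fresh dosage draws (int8 in {0,1,2}) from the blockwise-LD process."""
    m = len(structure)
    thresh = stats.norm.ppf(structure["freq"].to_numpy())
    out = np.empty((n, m), dtype=np.int8)
    a = config.ld_decay
    b = math.sqrt(1.0 - a * a)
    for blk, idx in structure.groupby("block", sort=True).indices.items():
        k = len(idx)
        geno = np.zeros((n, k), dtype=np.int8)
        for _hap in range(2):
            z = np.empty((n, k))
            z[:, 0] = rng.standard_normal(n)
            for j in range(1, k):
                z[:, j] = a * z[:, j - 1] + b * rng.standard_normal(n)
            geno += z < thresh[idx]
        out[:, idx] = geno
    return out


def simulate_reference_panel(config: SimulationConfig) -> GenotypePanel:
    """LD reference panel: dosages in {0,1,2} plus variant metadata."""
    structure = _structure(config)
    geno = _draw_genotypes(config, structure, config.n_ref, _rng(config, 2))
    variants = structure[["chrom", "pos", "id", "ea", "nea"]].copy()
    panel = GenotypePanel([f"ref{i:04d}" for i in range(config.n_ref)],
                          variants, geno.astype(float))
    panel.variants["eaf"] = panel.eaf()
    return panel


def simulate_architecture(config: SimulationConfig,
                          panel: GenotypePanel | None = None
                          ) -> TrueArchitecture:
    """Point-normal causal effects scaled to the target heritability.

    Effects are drawn Normal(0, h2/(M*p_causal)) at Bernoulli(p_causal) causal
    sites, then rescaled so the genetic variance over ``panel`` (or an
    internal fresh sample of 2000 when none is given) equals h2 exactly.
    """
    rng = _rng(config, 3)
    m = config.m_variants
    mask = rng.random(m) < config.p_causal
    if config.h2 == 0:
        return TrueArchitecture(mask, np.zeros(m))
    while not mask.any():  # tiny-M edge: a causal trait needs >= 1 causal site
        mask = rng.random(m) < config.p_causal
    beta = np.zeros(m)
    beta[mask] = rng.normal(
        0.0, math.sqrt(config.h2 / (m * config.p_causal)), mask.sum())
    if panel is None:
        structure = _structure(config)
        geno = _draw_genotypes(config, structure, 2000, _rng(config, 4))
        g = geno.astype(float) @ beta
    else:
        g = np.nan_to_num(panel.dosages) @ beta
    beta *= math.sqrt(config.h2 / g.var())
    return TrueArchitecture(mask, beta)


def simulate_gwas_summary(panel: GenotypePanel, arch: TrueArchitecture,
                          config: SimulationConfig) -> SummaryStats:
    """Marginal simple-regression GWAS on a fresh sample of size n_gwas.

    The trait is the unit-variance latent ln-scale value (genetic value plus
    Normal environmental noise).  Monomorphic variants have undefined SE and
    are excluded with a log record.
    """
    structure = _structure(config)
    rng = _rng(config, 5)
    geno = _draw_genotypes(config, structure, config.n_gwas, rng)
    x = geno.astype(float)
    n = config.n_gwas
    y = x @ arch.beta_true + rng.normal(0.0, math.sqrt(1.0 - config.h2), n)

    xm = x.mean(axis=0)
    sxx = ((x - xm) ** 2).sum(axis=0)
    poly = sxx > 0
    if (~poly).any():
        logger.info("simulate_gwas_summary: excluded %d monomorphic variants",
                    int((~poly).sum()))
    yc = y - y.mean()
    sxy = (x - xm).T @ yc
    beta = np.full(len(structure), np.nan)
    beta[poly] = sxy[poly] / sxx[poly]
    syy = float(yc @ yc)
    with np.errstate(invalid="ignore"):
        rss = syy - beta**2 * sxx
        se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / sxx)
    tval = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tval), df=n - 2)
    np.clip(pval, np.nextafter(0, 1), 1.0, out=pval)

    df = structure[["chrom", "pos", "id", "ea", "nea"]].copy()
    df["beta"], df["se"], df["p"] = beta, se, pval
    df["n"] = n
    df["eaf"] = xm / 2.0
    return SummaryStats(df[poly].reset_index(drop=True))


# ---------------------------------------------------------------------------
# cohorts

def simulate_cohorts(config: SimulationConfig, arch: TrueArchitecture,
                     specs: list[CohortSpec]) -> list[CohortTable]:
    """Fresh cohort draws with phenotypes, covariates, and role outcomes.

    Every cohort gets the four ln-scale lipid traits as
    ``mu_t + TRAIT_SD * (g + covariate effects + noise)`` with the shared
    genetic value g (variance h2) and independent per-trait environmental
    noise (variance 1 - h2); natural-scale traits are exponentials.
    Dyslipidemia labels use the configured clinical thresholds (adult
    defaults).  Role extras: longitudinal follow-up lipids, a log-normal
    cIMT-like outcome, or CHD case status from a logistic model in the
    standardized genetic value.
    """
    if not specs:
        raise ConfigurationError("no cohort specs given")
    structure = _structure(config)
    out = []
    for i, spec in enumerate(specs):
        rng = _rng(config, 10, i)
        out.append(_one_cohort(config, arch, structure, spec, rng))
    return out


def _one_cohort(config, arch, structure, spec, rng) -> CohortTable:
    from . import evaluate  # deferred: avoids module import cycle

    n = spec.n
    geno = _draw_genotypes(config, structure, n, rng).astype(float)
    g = geno @ arch.beta_true
    g_sd = math.sqrt(config.h2) if config.h2 > 0 else 1.0

    df = pd.DataFrame({
        "sample": [f"{spec.label}_{i:05d}" for i in range(n)],
        "sex": rng.integers(0, 2, n),
        "age": rng.normal(50.0, 10.0, n).round(1),
        "bmi": rng.normal(24.0, 3.0, n).round(2),
        "sbp": rng.normal(125.0, 15.0, n).round(1),
        "duration_dm": (10.0 + rng.exponential(5.0, n)).round(1),
        "smoking": rng.random(n) < 0.25,
        "hba1c": rng.normal(7.5, 1.2, n).round(2),
        "egfr": rng.normal(80.0, 20.0, n).round(1),
        "ln_acr": rng.normal(1.0, 1.5, n).round(3),
        "lipid_drug": rng.random(n) < 0.4,
    })
    for k in range(1, 5):
        df[f"pc{k}"] = rng.standard_normal(n)

    ce = spec.covariate_effects
    covar = (ce.get("sex", 0.0) * df["sex"].to_numpy()
             + ce.get("age", 0.0) * (df["age"].to_numpy() - 50.0)
             + ce.get("bmi", 0.0) * (df["bmi"].to_numpy() - 24.0))
    env_sd = math.sqrt(1.0 - config.h2)
    noise = {t: rng.normal(0.0, env_sd, n) for t in TRAIT_MU}
    for t, mu in TRAIT_MU.items():
        df[t] = np.exp(mu + TRAIT_SD * (g + noise[t] + covar))

    age_group = spec.outcome_params.get("age_group", "adult")
    labels = evaluate.dyslipidemia_labels(
        df[["tc", "tg", "hdl", "ldl"]], age_group)
    for col in labels.columns:
        df[col] = labels[col]

    if spec.role == "longitudinal":
        tracking = spec.outcome_params.get("tracking", 0.7)
        drift = spec.outcome_params.get("drift", 0.0)
        ortho = math.sqrt(max(0.0, 1.0 - tracking**2))
        for t, mu in TRAIT_MU.items():
            e_fu = tracking * noise[t] + ortho * rng.normal(0.0, env_sd, n)
            df[f"{t}_fu"] = np.exp(mu + drift + TRAIT_SD * (g + e_fu + covar))
    elif spec.role == "cimt":
        b = spec.outcome_params.get("beta_per_sd", 0.02)
        sd = spec.outcome_params.get("noise_sd", 0.15)
        df["cimt"] = np.exp(math.log(0.05) + b * g / g_sd
                            + 0.004 * (df["age"] - 50.0)
                            + rng.normal(0.0, sd, n))
    elif spec.role == "chd":
        log_or = spec.outcome_params.get("log_or_per_sd", math.log(1.15))
        prev = spec.outcome_params.get("prevalence", 0.275)
        eta = (math.log(prev / (1 - prev)) + log_or * g / g_sd
               + 0.02 * (df["age"] - 50.0) + 0.3 * df["sex"])
        df["chd"] = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

    variants = structure[["chrom", "pos", "id", "ea", "nea"]].copy()
    panel = GenotypePanel(df["sample"].tolist(), variants, geno)
    panel.variants["eaf"] = panel.eaf()
    return CohortTable(spec.label, spec.role, df, panel, g)


# ---------------------------------------------------------------------------
# writers

def write_architecture(arch: TrueArchitecture, structure_or_panel, path) -> None:
    """Ground-truth effects as tab-delimited text (test oracle file)."""
    variants = getattr(structure_or_panel, "variants", structure_or_panel)
    pd.DataFrame({
        "ID": variants["id"], "CAUSAL": arch.causal_mask.astype(int),
        "BETA_TRUE": arch.beta_true,
    }).to_csv(path, sep="\t", index=False)


def write_cohort_csv(cohort: CohortTable, path) -> None:
    cohort.table.to_csv(path, index=False)
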