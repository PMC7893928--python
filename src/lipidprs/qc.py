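"""Allele harmonization and per-marker / per-sample genotype quality control.

Filters follow array-QC convention: call rate, MAF, a stricter call-rate rule
for low-frequency variants (MAF in [1%, 5%] requires >= 99% call rate), an
exact Hardy-Weinberg test, and an optional imputation-quality cutoff.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypePanel, SummaryStats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class QcReport:
    """Per-stage removal counts; retained + removed = input at every stage."""

    params: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)  # stage -> removed count
    n_input: int = 0
    n_retained: int = 0

    def record(self, stage: str, removed: int) -> None:
        self.stages[stage] = self.stages.get(stage, 0) + int(removed)

    @property
    def n_removed(self) -> int:
        return sum(self.stages.values())


def harmonize(ss: SummaryStats, panel: GenotypePanel) -> tuple[SummaryStats, QcReport]:
    """Match summary statistics to a panel by chrom:pos and align alleles.

    Strand-ambiguous (A/T, C/G) variants are removed.  A direct allele match
    keeps the effect sign; swapped alleles flip the sign of beta; a
    strand-flipped pair is matched after complementing both alleles.  Anything
    unmatched or inconsistent is dropped.  Output rows follow panel variant
    order, so downstream code may align by position index.
    """
    report = QcReport(params={"op": "harmonize"}, n_input=len(ss))
    df = ss.table
    ambiguous = df.apply(lambda r: COMPLEMENT.get(r.ea) == r.nea, axis=1) \
        if len(df) else pd.Series([], dtype=bool)
    report.record("strand_ambiguous", int(ambiguous.sum()))
    df = df[~ambiguous]

    panel_idx = {(c, p): k for k, (c, p) in
                 enumerate(zip(panel.variants["chrom"], panel.variants["pos"]))}
    keep_rows: list[tuple[int, pd.Series, float]] = []  # (panel idx, row, sign)
    n_unmatched = n_inconsistent = 0
    for _, row in df.iterrows():
        k = panel_idx.get((row.chrom, row.pos))
        if k is None:
            n_unmatched += 1
            continue
        pa = panel.variants["ea"].iat[k]
        pb = panel.variants["nea"].iat[k]
        sign = _allele_sign(row.ea, row.nea, pa, pb)
        if sign is None:
            n_inconsistent += 1
            continue
        keep_rows.append((k, row, sign))
    report.record("unmatched_position", n_unmatched)
    report.record("allele_mismatch", n_inconsistent)

    keep_rows.sort(key=lambda t: t[0])
    out = []
    for k, row, sign in keep_rows:
        rec = row.copy()
        rec["ea"] = panel.variants["ea"].iat[k]
        rec["nea"] = panel.variants["nea"].iat[k]
        rec["beta"] = sign * row.beta
        if "eaf" in rec.index and pd.notna(rec.get("eaf")) and sign < 0:
            rec["eaf"] = 1.0 - rec["eaf"]
        out.append(rec)
    table = (pd.DataFrame(out).reset_index(drop=True) if out
             else ss.table.iloc[:0].copy())
    report.n_retained = len(table)
    return SummaryStats(table), report


def _allele_sign(ea, nea, panel_ea, panel_nea):
    """+1 if (ea, nea) aligns with panel orientation, -1 if swapped, None if
    irreconcilable.  Strand flips are resolved by complementing."""
    if (ea, nea) == (panel_ea, panel_nea):
        return 1.0
    if (ea, nea) == (panel_nea, panel_ea):
        return -1.0
    cea, cnea = COMPLEMENT.get(ea), COMPLEMENT.get(nea)
    if (cea, cnea) == (panel_ea, panel_nea):
        return 1.0
    if (cea, cnea) == (panel_nea, panel_ea):
        return -1.0
    return None


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value for one biallelic variant.

    Sums, over the conditional distribution of the heterozygote count given
    the allele counts, the probabilities of all heterozygote counts no more
    probable than the observed one (the standard SNP-HWE tail definition,
    no mid-p correction).  Monomorphic input returns 1.0.
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_a + n_het + n_hom_b
    if n < 1:
        raise ValueError("empty genotype table")
    rare = 2 * min(n_hom_a, n_hom_b) + n_het
    if rare == 0 or rare == 2 * n:
        return 1.0
    # log P(het = h | allele counts) up to a shared constant
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (hets * math.log(2)
            - _lgamma_arr(hets + 1) - _lgamma_arr(hom_r + 1)
            - _lgamma_arr(hom_c + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def _lgamma_arr(x):
    from scipy.special import gammaln
    return gammaln(np.asarray(x, dtype=float))


def qc_variants(panel: GenotypePanel, maf_min: float = 0.01,
                hwe_p_min: float = 1e-4, call_rate_min: float = 0.95,
                call_rate_min_lowfreq: float = 0.99,
                impute_r2_min: float | None = None,
                ) -> tuple[GenotypePanel, QcReport]:
    """Per-marker filters, applied in a fixed order so removal counts are
    reproducible: call rate -> MAF -> low-frequency call rate -> HWE ->
    imputation r2.  The low-frequency rule removes variants with MAF in
    [maf_min, 0.05] whose call rate is below ``call_rate_min_lowfreq``.
    """
    report = QcReport(params={
        "maf_min": maf_min, "hwe_p_min": hwe_p_min,
        "call_rate_min": call_rate_min,
        "call_rate_min_lowfreq": call_rate_min_lowfreq,
        "impute_r2_min": impute_r2_min,
    }, n_input=panel.n_variants)

    d = panel.dosages
    call_rate = 1.0 - np.isnan(d).mean(axis=0)
    keep = call_rate >= call_rate_min
    report.record("call_rate", int((~keep).sum()))

    eaf = panel.eaf()
    maf = np.minimum(eaf, 1.0 - eaf)
    fail = keep & (maf < maf_min)
    report.record("maf", int(fail.sum()))
    keep &= ~fail

    lowfreq = keep & (maf >= maf_min) & (maf <= 0.05)
    fail = lowfreq & (call_rate < call_rate_min_lowfreq)
    report.record("call_rate_lowfreq", int(fail.sum()))
    keep &= ~fail

    fail = np.zeros_like(keep)
    for k in np.flatnonzero(keep):
        col = d[:, k]
        col = col[~np.isnan(col)]
        g = np.rint(col).astype(int)
        n_bb = int((g == 0).sum())
        n_ab = int((g == 1).sum())
        n_aa = int((g == 2).sum())
        if hwe_exact_test(n_aa, n_ab, n_bb) < hwe_p_min:
            fail[k] = True
    report.record("hwe", int(fail.sum()))
    keep &= ~fail

    if impute_r2_min is not None and "impute_r2" in panel.variants.columns:
        r2 = panel.variants["impute_r2"].to_numpy(float)
        fail = keep & ~np.isnan(r2) & (r2 < impute_r2_min)
        report.record("impute_r2", int(fail.sum()))
        keep &= ~fail

    out = panel.subset_variants(keep)
    report.n_retained = out.n_variants
    return out, report


def qc_samples(panel: GenotypePanel, het_sd: float = 3.0,
               call_rate_min: float = 0.95) -> tuple[GenotypePanel, QcReport]:
    """Remove samples with low call rate or outlying heterozygosity rate
    (beyond ``het_sd`` standard deviations of the across-sample mean)."""
    if panel.n_samples < 5:
        raise ValueError("sample QC needs at least 5 samples")
    report = QcReport(params={"het_sd": het_sd, "call_rate_min": call_rate_min},
                      n_input=panel.n_samples)
    d = panel.dosages
    call_rate = 1.0 - np.isnan(d).mean(axis=1)
    keep = call_rate >= call_rate_min
    report.record("call_rate", int((~keep).sum()))

    with np.errstate(invalid="ignore"):
        het = np.nanmean(np.rint(d) == 1, axis=1)
    mu, sd = het[keep].mean(), het[keep].std()
    if sd > 0:
        fail = keep & (np.abs(het - mu) > het_sd * sd)
    else:
        fail = np.zeros_like(keep)
    report.record("heterozygosity", int(fail.sum()))
    keep &= ~fail

    out = panel.subset_samples(keep)
    report.n_retained = out.n_samples
    return out, report


def compute_pcs(panel: GenotypePanel, k: int) -> np.ndarray:
    """Principal-component coordinates of samples from standardized dosages.

    Missing dosages are mean-imputed per variant; zero-variance variants are
    dropped before standardization.  Columns are ordered by decreasing
    explained variance with a deterministic sign (the largest-magnitude
    loading of each component is made positive).
    """
    if k >= min(panel.n_samples, panel.n_variants):
        raise ValueError("k must be < min(n_samples, n_variants)")
    x = panel.dosages.astype(float).copy()
    mu = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    x[nan_mask] = np.take(mu, np.nonzero(nan_mask)[1])
    sd = x.std(axis=0)
    poly = sd > 0
    if not poly.any():
        raise ValueError("degenerate panel: all variants monomorphic")
    x = (x[:, poly] - mu[poly]) / sd[poly]
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            coords[:, j] *= -1
    return coords
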