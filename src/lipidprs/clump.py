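"""Pruning-and-thresholding PRS derivation and weighted-sum scoring.

The clumping procedure is the greedy PLINK-style algorithm: among variants
passing the p-value threshold, repeatedly take the most significant remaining
variant as an index and discard every remaining same-chromosome variant within
the physical window whose LD with the index reaches the r2 cutoff.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypePanel, SummaryStats, WeightSet

logger = logging.getLogger(__name__)

#: the 9 x 3 derivation grid: p-value and r2 thresholds
P_GRID = (1.0, 0.5, 0.1, 0.05, 0.01, 1e-3, 1e-4, 1e-5, 5e-8)
R2_GRID = (0.2, 0.4, 0.6)


@dataclass(frozen=True)
class ClumpConfig:
    p_threshold: float
    r2_threshold: float
    window_kb: float = 250.0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


def ld_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation between two dosage columns.

    Missing dosages are excluded pairwise; a monomorphic variant has no
    defined LD and raises.
    """
    x, y = panel.dosages[:, i], panel.dosages[:, j]
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        raise ValueError(f"undefined LD: variant {i if x.std() == 0 else j} "
                         "is monomorphic")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def clump(ss: SummaryStats, panel: GenotypePanel, cfg: ClumpConfig) -> WeightSet:
    """Greedy LD clumping; returns index variants weighted by their GWAS beta.

    Requires ``ss`` already harmonized to ``panel``.  Ties in p are broken by
    (chrom, pos) ascending so output is invariant to input row order.  Output
    is ordered by chrom, pos.
    """
    df = ss.table
    df = df[df["p"] <= cfg.p_threshold]
    if df.empty:
        logger.warning("clump: no variant passes p <= %g", cfg.p_threshold)
        return WeightSet(df[["chrom", "pos", "id", "ea", "nea"]].copy(),
                         np.empty(0), _prov(cfg, 0))

    pos_key = {(c, p): k for k, (c, p) in
               enumerate(zip(panel.variants["chrom"], panel.variants["pos"]))}
    cand = df.assign(_panel_idx=[pos_key.get((c, p)) for c, p in
                                 zip(df["chrom"], df["pos"])])
    if cand["_panel_idx"].isna().any():
        raise ValueError("summary statistics not harmonized to panel")
    cand = cand.sort_values(["p", "chrom", "pos"], kind="mergesort")

    window = cfg.window_kb * 1000.0
    dose = panel.dosages
    # per-candidate arrays in significance order
    chrom = cand["chrom"].to_numpy()
    pos = cand["pos"].to_numpy(float)
    pidx = cand["_panel_idx"].to_numpy(int)
    alive = np.ones(len(cand), dtype=bool)
    chosen: list[int] = []
    for i in range(len(cand)):
        if not alive[i]:
            continue
        chosen.append(i)
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        near[i] = False
        js = np.flatnonzero(near)
        if len(js):
            x = dose[:, pidx[i]]
            y = dose[:, pidx[js]]
            r2 = _pairwise_r2(x, y)
            alive[js[r2 >= cfg.r2_threshold]] = False
        alive[i] = False

    out = cand.iloc[chosen].sort_values(["chrom", "pos"]).reset_index(drop=True)
    variants = out[["chrom", "pos", "id", "ea", "nea"]].copy()
    return WeightSet(variants, out["beta"].to_numpy(float),
                     _prov(cfg, len(out)))


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """r2 of column vector x against each column of y, pairwise-complete."""
    out = np.empty(y.shape[1])
    x_ok = ~np.isnan(x)
    for c in range(y.shape[1]):
        ok = x_ok & ~np.isnan(y[:, c])
        xv, yv = x[ok], y[ok, c]
        if xv.std() == 0 or yv.std() == 0:
            out[c] = 0.0
        else:
            r = np.corrcoef(xv, yv)[0, 1]
            out[c] = r * r
    return out


def _prov(cfg: ClumpConfig, n: int) -> dict:
    return {"method": "pt", "p_threshold": cfg.p_threshold,
            "r2_threshold": cfg.r2_threshold, "window_kb": cfg.window_kb,
            "n_variants": n}


def grid_candidates(ss: SummaryStats, panel: GenotypePanel,
                    window_kb: float = 250.0) -> list[WeightSet]:
    """All 27 pruning-and-thresholding candidates (3 r2 x 9 p thresholds)."""
    return [clump(ss, panel, ClumpConfig(p, r2, window_kb))
            for r2 in R2_GRID for p in P_GRID]


def score(panel: GenotypePanel, ws: WeightSet) -> np.ndarray:
    """Per-sample PRS: the weighted sum of effect-allele dosages.

    A weight on the allele the panel counts as "other" contributes via the
    reflected dosage 2 - d.  Missing dosages are imputed with twice the panel
    effect-allele frequency.  Weight-set variants absent from the panel are
    skipped with a logged count; zero overlap is an error.
    """
    pos_key = {(c, p): k for k, (c, p) in
               enumerate(zip(panel.variants["chrom"], panel.variants["pos"]))}
    eaf = panel.eaf()
    total = np.zeros(panel.n_samples)
    n_used = n_skipped = 0
    for k in range(len(ws)):
        row = ws.variants.iloc[k]
        j = pos_key.get((row.chrom, row.pos))
        if j is None:
            n_skipped += 1
            continue
        pa, pb = panel.variants["ea"].iat[j], panel.variants["nea"].iat[j]
        if row.ea == pa:
            d = panel.dosages[:, j]
            fill = 2.0 * eaf[j]
        elif row.ea == pb:
            d = 2.0 - panel.dosages[:, j]
            fill = 2.0 * (1.0 - eaf[j])
        else:
            n_skipped += 1
            continue
        d = np.where(np.isnan(d), fill, d)
        total += ws.weights[k] * d
        n_used += 1
    if n_used == 0:
        raise ValueError("no weight-set variant overlaps the panel")
    if n_skipped:
        logger.info("score: skipped %d weight-set variants absent from panel",
                    n_skipped)
    return total
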