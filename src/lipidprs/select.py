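"""Candidate validation, Fisher-Z pooled correlation, and score selection.

Every candidate weight set is scored in every validation cohort; per-cohort
Pearson correlations with the ln-transformed trait are pooled on the Fisher-Z
scale with weights (n - 3) and the candidate with maximal pooled correlation
is flagged best.  The winning score is z-standardized and cut into quintiles
using mean/SD and percentile thresholds from a designated reference cohort.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clump import score
from .io import WeightSet
from .sim import CohortTable


@dataclass
class CorrelationResult:
    cohort: str
    n: int
    r_pearson: float
    r_spearman: float

    @property
    def z(self) -> float:
        return math.atanh(self.r_pearson)


def cohort_correlations(prs: np.ndarray, trait: np.ndarray,
                        cohort_label: str) -> CorrelationResult:
    """Pearson and Spearman (average-rank ties) correlation of PRS with a
    trait in one cohort, over paired non-missing values."""
    prs = np.asarray(prs, float)
    trait = np.asarray(trait, float)
    ok = ~np.isnan(prs) & ~np.isnan(trait)
    prs, trait = prs[ok], trait[ok]
    if len(prs) < 4:
        raise ValueError("need at least 4 paired observations")
    if prs.std() == 0 or trait.std() == 0:
        raise ValueError("undefined correlation: zero-variance input")
    r_p = float(np.corrcoef(prs, trait)[0, 1])
    r_s = float(stats.spearmanr(prs, trait).statistic)
    return CorrelationResult(cohort_label, len(prs), r_p, r_s)


def pool_fisher(results: list[CorrelationResult]) -> float:
    """Pooled correlation: inverse-variance average on the Fisher-Z scale
    (weight n - 3 per cohort), back-transformed by tanh."""
    if not results:
        raise ValueError("no correlations to pool")
    for res in results:
        if abs(res.r_pearson) >= 1.0:
            raise ValueError(f"infinite Fisher z in cohort {res.cohort}")
        if res.n < 4:
            raise ValueError("each cohort needs n >= 4")
    w = np.array([res.n - 3 for res in results], float)
    z = np.array([res.z for res in results])
    return float(math.tanh((w * z).sum() / w.sum()))


@dataclass
class SelectionTable:
    table: pd.DataFrame  # one row per candidate, ranked
    correlations: dict   # candidate index -> list[CorrelationResult]

    @property
    def best_index(self) -> int:
        return int(self.table.loc[self.table["best"], "candidate"].iloc[0])


def select_best(candidates: list[WeightSet],
                cohorts: list[CohortTable],
                trait: str = "tc") -> SelectionTable:
    """Score every candidate in every validation cohort and rank by pooled
    Pearson correlation with the ln-transformed trait.

    Ties are broken by fewer variants, then by candidate order.  Exactly one
    candidate is flagged best.
    """
    if not candidates or not cohorts:
        raise ValueError("need at least one candidate and one cohort")
    rows, all_corr = [], {}
    for ci, ws in enumerate(candidates):
        corrs = []
        for cohort in cohorts:
            if len(ws) == 0:
                corrs = []
                break
            prs = score(cohort.panel, ws)
            ln_trait = np.log(cohort.table[trait].to_numpy(float))
            corrs.append(cohort_correlations(prs, ln_trait, cohort.label))
        pooled = pool_fisher(corrs) if corrs else -np.inf
        all_corr[ci] = corrs
        rows.append({"candidate": ci, "pooled_r": pooled,
                     "n_variants": len(ws), **ws.provenance})
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["pooled_r", "n_variants", "candidate"],
        ascending=[False, True, True], kind="mergesort")
    table["rank"] = 0
    table.loc[order.index, "rank"] = np.arange(1, len(table) + 1)
    table["best"] = table["rank"] == 1
    return SelectionTable(table.sort_values("rank").reset_index(drop=True),
                          all_corr)


@dataclass
class StandardizedScore:
    z_value: np.ndarray
    quintile: np.ndarray  # ordinal 1-5


def standardize_and_quintile(prs_values: np.ndarray,
                             reference_values: np.ndarray
                             ) -> StandardizedScore:
    """z-standardize and bin a score using a reference cohort's parameters.

    Mean/SD and the 20/40/60/80th percentile cut points come from the
    reference cohort only; quintile intervals are right-closed,
    (-inf, q20], (q20, q40], (q40, q60], (q60, q80], (q80, inf).
    """
    ref = np.asarray(reference_values, float)
    if len(ref) < 50:
        raise ValueError("reference cohort needs n >= 50")
    mu, sd = ref.mean(), ref.std()
    if sd == 0:
        raise ValueError("degenerate reference cohort: zero score variance")
    x = np.asarray(prs_values, float)
    cuts = np.quantile(ref, [0.2, 0.4, 0.6, 0.8])
    quintile = 1 + np.searchsorted(cuts, x, side="left")
    return StandardizedScore((x - mu) / sd, quintile.astype(int))


def variance_explained(trait: np.ndarray, prs: np.ndarray,
                       covariates: np.ndarray | None) -> float:
    """Incremental R2 of the PRS: R2(trait ~ PRS + covariates) minus
    R2(trait ~ covariates), both by least squares."""
    y = np.asarray(trait, float)
    n = len(y)
    base = (np.column_stack([np.ones(n), covariates])
            if covariates is not None and np.size(covariates)
            else np.ones((n, 1)))
    full = np.column_stack([base, prs])
    if n <= full.shape[1] + 1:
        raise ValueError("too few observations for the model")
    if np.linalg.matrix_rank(full) < full.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    return _r2(y, full) - _r2(y, base)


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("zero-variance outcome")
    return 1.0 - float((resid**2).sum() / tss)
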