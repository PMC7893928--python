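"""Clinical evaluation of polygenic scores.

Trait/outcome transformations (Friedewald LDL, clinical dyslipidemia labels,
ln(1+Y) relative change), covariate-ladder linear and logistic association
models, fixed-effects inverse-variance meta-analysis with Cochran's Q,
discrimination (Mann-Whitney AUC, DeLong correlated-AUC comparison, delta-AUC
of adding the PRS to clinical factors), top-20% diagnostic metrics, and the
quintile trend / tail tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: clinical dyslipidemia thresholds in mmol/l by age group; each entry is
#: (column, label, cutoff).  Adults carry both TG and both LDL cutoffs.
DYSLIPIDEMIA_THRESHOLDS = {
    "child": [("tc", "dys_tc", 5.1), ("tg", "dys_tg", 1.1),
              ("ldl", "dys_ldl", 3.4)],
    "adolescent": [("tc", "dys_tc", 5.1), ("tg", "dys_tg", 1.4),
                   ("ldl", "dys_ldl", 3.4)],
    "adult": [("tc", "dys_tc", 5.2),
              ("tg", "dys_tg", 1.7), ("tg", "dys_tg_1p97", 1.97),
              ("ldl", "dys_ldl_1p8", 1.8), ("ldl", "dys_ldl", 2.6)],
}


@dataclass
class AssocResult:
    beta: float
    se: float
    p: float
    n: int
    model_id: str = ""
    note: str = ""

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def or_ci(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return (math.exp(self.beta - z * self.se),
                math.exp(self.beta + z * self.se))


@dataclass
class MetaResult:
    beta: float
    se: float
    p: float
    q_stat: float
    p_q: float
    k: int


@dataclass
class DiagnosticResult:
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    note: str = "positive prediction = PRS above cohort 80th percentile"


@dataclass
class DeltaAucResult:
    auc_m1: float  # clinical factors + PCs
    auc_m2: float  # PRS only
    auc_m3: float  # clinical factors + PCs + PRS
    delta: float   # auc_m3 - auc_m1
    p_delong: float


# ---------------------------------------------------------------------------
# outcome transformations

def friedewald_ldl(tc, hdl, tg):
    """LDL-C = TC - HDL-C - TG/2.2 (mmol/l), only valid for TG < 4.5;
    otherwise the result is missing (NaN), never a number."""
    tc, hdl, tg = (np.asarray(v, float) for v in (tc, hdl, tg))
    ldl = np.where(tg < 4.5, tc - hdl - tg / 2.2, np.nan)
    return float(ldl) if ldl.ndim == 0 else ldl


def dyslipidemia_labels(panel: pd.DataFrame, age_group: str,
                        thresholds: dict | None = None) -> pd.DataFrame:
    """Boolean abnormal-lipid labels at the clinical cutoffs for an age group.

    ``panel`` needs natural-scale columns among tc/tg/hdl/ldl; adults get
    both TG cutoffs (1.7 primary, 1.97 as ``dys_tg_1p97``) and both LDL
    cutoffs (2.6 primary, 1.8 as ``dys_ldl_1p8``).
    """
    table = thresholds or DYSLIPIDEMIA_THRESHOLDS
    if age_group not in table:
        raise ValueError(f"unknown age group {age_group!r}")
    out = pd.DataFrame(index=panel.index)
    for col, label, cutoff in table[age_group]:
        if col in panel.columns:
            out[label] = panel[col].to_numpy(float) >= cutoff
    return out


def relative_change(baseline, followup):
    """ln(1 + Y) of the relative change Y = (followup - baseline)/baseline."""
    baseline = np.asarray(baseline, float)
    followup = np.asarray(followup, float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be positive")
    y = (followup - baseline) / baseline
    if np.any(y <= -1):
        raise ValueError("relative change <= -1 outside ln(1+Y) domain")
    out = np.log1p(y)
    return float(out) if out.ndim == 0 else out


def percent_per_sd(beta_ln_scale: float) -> float:
    """Percent change in the natural-scale trait per 1-SD increase in PRS,
    from an ln-scale coefficient: 100*(exp(beta) - 1), to one decimal."""
    return round(100.0 * math.expm1(beta_ln_scale), 1)


# ---------------------------------------------------------------------------
# association models

def _design(exposure, covariates, n):
    cols = [np.ones(n), np.asarray(exposure, float)]
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, float)
        cols.append(cov.reshape(n, -1))
    return np.column_stack(cols)


def linear_assoc(outcome, exposure, covariates=None,
                 model_id: str = "") -> AssocResult:
    """OLS of the (caller-transformed, typically ln) outcome on the exposure
    plus covariates; reports the exposure coefficient with its SE and
    two-sided t-test p-value."""
    y = np.asarray(outcome, float)
    x = _design(exposure, covariates, len(y))
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    fit = sm.OLS(y, x).fit()
    note = "zero residual variance" if fit.ssr <= 1e-12 * len(y) else ""
    beta, se = float(fit.params[1]), float(fit.bse[1])
    if se == 0 or not np.isfinite(se):  # degenerate (exact) fit
        p = 1.0 if beta == 0 else 0.0
    else:
        p = float(np.clip(fit.pvalues[1], 0, 1))
    return AssocResult(beta, se, p, len(y), model_id, note)


def logistic_assoc(case_flag, exposure, covariates=None,
                   model_id: str = "") -> AssocResult:
    """Maximum-likelihood logistic regression; reports the exposure log-OR,
    SE, and Wald p.  Perfect separation raises rather than returning silent
    estimates."""
    y = np.asarray(case_flag, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    x = _design(exposure, covariates, len(y))
    model = sm.Logit(y, x)
    model.raise_on_perfect_prediction = True
    try:
        fit = model.fit(disp=0, maxiter=200, tol=1e-10)
    except Exception as exc:
        raise RuntimeError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("logistic fit did not converge (separation?)")
    return AssocResult(float(fit.params[1]), float(fit.bse[1]),
                       float(np.clip(fit.pvalues[1], 0, 1)), len(y), model_id)


def meta_fixed(results: list[AssocResult]) -> MetaResult:
    """Inverse-variance fixed-effects pooling with Cochran's Q heterogeneity."""
    if not results:
        raise ValueError("no results to meta-analyze")
    beta = np.array([r.beta for r in results])
    se = np.array([r.se for r in results])
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled = float((w * beta).sum() / w.sum())
    pooled_se = float(1.0 / math.sqrt(w.sum()))
    z = pooled / pooled_se
    p = float(2.0 * stats.norm.sf(abs(z)))
    q = float((w * (beta - pooled) ** 2).sum())
    k = len(results)
    p_q = float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0
    return MetaResult(pooled, pooled_se, p, q, p_q, k)


# ---------------------------------------------------------------------------
# discrimination

def auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_case = int(labels.sum())
    n_ctrl = int((~labels).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_case * (n_case + 1) / 2.0
    return float(u / (n_case * n_ctrl))


def _delong_components(scores, labels):
    """Per-case and per-control structural components of the AUC."""
    x = scores[labels]          # cases
    y = scores[~labels]         # controls
    # psi(x_i, y_j) = 1[x>y] + 0.5*1[x==y], vectorized via rank arithmetic
    order = np.concatenate([x, y])
    ranks = stats.rankdata(order)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    m, n = len(x), len(y)
    v10 = (ranks[:m] - rx) / n
    v01 = 1.0 - (ranks[m:] - ry) / m
    return v10, v01


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong comparison of two correlated AUCs computed on the
    same samples.  Returns (auc_a - auc_b, p).  A self-comparison has zero
    variance and p = 1 by convention."""
    labels = np.asarray(labels).astype(bool)
    sa = np.asarray(scores_a, float)
    sb = np.asarray(scores_b, float)
    auc_a, auc_b = auc(sa, labels), auc(sb, labels)
    v10a, v01a = _delong_components(sa, labels)
    v10b, v01b = _delong_components(sb, labels)
    m, n = len(v10a), len(v01a)
    var = (np.var(v10a - v10b, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01a - v01b, ddof=1) / n if n > 1 else 0.0)
    delta = auc_a - auc_b
    if var <= 0:
        return float(delta), 1.0 if abs(delta) < 1e-12 else 0.0
    z = delta / math.sqrt(var)
    return float(delta), float(2.0 * stats.norm.sf(abs(z)))


def delta_auc(outcome, prs_z, clinical_covariates, pcs) -> DeltaAucResult:
    """AUC gain from adding the PRS to clinical factors.

    Fits three logistic models on the same samples — model 1: clinical
    covariates + PCs; model 2: PRS only; model 3: model 1 + PRS — computes
    each AUC on fitted probabilities, and compares models 3 and 1 with the
    DeLong test.  delta = AUC(m3) - AUC(m1).
    """
    y = np.asarray(outcome, float)
    n = len(y)
    clin = np.asarray(clinical_covariates, float).reshape(n, -1)
    pcs = np.asarray(pcs, float).reshape(n, -1)
    base = np.column_stack([clin, pcs])
    prs_z = np.asarray(prs_z, float)

    p1 = _fitted_probs(y, base)
    p2 = _fitted_probs(y, prs_z.reshape(-1, 1))
    p3 = _fitted_probs(y, np.column_stack([base, prs_z]))
    labels = y.astype(bool)
    delta, p_delong = delong_test(p3, p1, labels)
    return DeltaAucResult(auc(p1, labels), auc(p2, labels), auc(p3, labels),
                          delta, p_delong)


def _fitted_probs(y, covars) -> np.ndarray:
    x = np.column_stack([np.ones(len(y)), covars])
    fit = sm.Logit(y, x).fit(disp=0, maxiter=200, tol=1e-10)
    return np.asarray(fit.predict(x))


# ---------------------------------------------------------------------------
# diagnostics and quintile tests

def diagnostics_top20(prs_z, case_flag) -> DiagnosticResult:
    """PPV/NPV/sensitivity/specificity of the top-20%-of-PRS decision rule.

    A positive prediction is a PRS above the cohort's own 80th percentile.
    Metrics with an empty margin are reported as NaN.
    """
    prs_z = np.asarray(prs_z, float)
    y = np.asarray(case_flag).astype(bool)
    if len(y) < 10:
        raise ValueError("need n >= 10")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    positive = prs_z > np.quantile(prs_z, 0.8)
    tp = int((positive & y).sum())
    fp = int((positive & ~y).sum())
    fn = int((~positive & y).sum())
    tn = int((~positive & ~y).sum())

    def _ratio(a, b):
        return a / b if b > 0 else float("nan")

    return DiagnosticResult(
        ppv=_ratio(tp, tp + fp), npv=_ratio(tn, tn + fn),
        sensitivity=_ratio(tp, tp + fn), specificity=_ratio(tn, tn + fp))


def quintile_tests(outcome, quintile, covariates=None,
                   outcome_type: str = "linear"
                   ) -> tuple[AssocResult, AssocResult, AssocResult]:
    """The three quintile estimands: (a) linear trend with the quintile
    entered as ordinal 1-5, (b) top 20% (quintile 5) vs the rest, (c) bottom
    20% (quintile 1) vs the rest; linear or logistic per ``outcome_type``."""
    q = np.asarray(quintile, int)
    if set(np.unique(q)) != {1, 2, 3, 4, 5}:
        raise ValueError("all five quintiles must be populated")
    fit = {"linear": linear_assoc, "logistic": logistic_assoc}[outcome_type]
    trend = fit(outcome, q.astype(float), covariates, model_id="trend")
    top = fit(outcome, (q == 5).astype(float), covariates, model_id="top20")
    bottom = fit(outcome, (q == 1).astype(float), covariates,
                 model_id="bottom20")
    return trend, top, bottom
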