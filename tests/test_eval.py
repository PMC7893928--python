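"""Clinical-evaluation stack: transformations, association models,
meta-analysis, discrimination, diagnostics, quintile tests."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidprs.evaluate import (AssocResult, auc, delong_test, delta_auc,
                               diagnostics_top20, dyslipidemia_labels,
                               friedewald_ldl, linear_assoc, logistic_assoc,
                               meta_fixed, percent_per_sd, quintile_tests,
                               relative_change)


# ---------------------------------------------------------------------------
# transformations

def test_friedewald_formula():
    assert friedewald_ldl(5.2, 1.0, 2.2) == pytest.approx(3.2)
    assert friedewald_ldl(4.0, 4.0, 0.0) == pytest.approx(0.0)
    assert np.isnan(friedewald_ldl(5.2, 1.0, 4.5))  # TG >= 4.5: not computable
    out = friedewald_ldl([5.2, 6.0], [1.0, 1.2], [2.2, 5.0])
    assert out[0] == pytest.approx(3.2) and np.isnan(out[1])


@pytest.mark.parametrize("group,col,value,expected", [
    ("adult", "tc", 5.3, True), ("adult", "tc", 5.1, False),
    ("adolescent", "tg", 1.2, False), ("adolescent", "tg", 1.4, True),
    ("child", "tg", 1.1, True),
    ("child", "ldl", 3.3, False), ("adult", "ldl", 2.6, True),
])
def test_dyslipidemia_thresholds(group, col, value, expected):
    panel = pd.DataFrame({col: [value]})
    labels = dyslipidemia_labels(panel, group)
    assert labels[f"dys_{col}"].iloc[0] == expected


def test_dyslipidemia_adult_dual_cutoffs_and_errors():
    panel = pd.DataFrame({"tg": [1.8], "ldl": [2.0]})
    labels = dyslipidemia_labels(panel, "adult")
    assert labels["dys_tg"].iloc[0] and not labels["dys_tg_1p97"].iloc[0]
    assert labels["dys_ldl_1p8"].iloc[0] and not labels["dys_ldl"].iloc[0]
    with pytest.raises(ValueError):
        dyslipidemia_labels(panel, "elder")


def test_relative_change():
    assert relative_change(4.0, 5.0) == pytest.approx(math.log(1.25))
    assert relative_change(3.3, 3.3) == 0.0
    assert relative_change(2.0, 1.0) == pytest.approx(math.log(0.5))
    with pytest.raises(ValueError):
        relative_change(0.0, 1.0)
    with pytest.raises(ValueError):
        relative_change(2.0, -0.1)


def test_percent_per_sd_printed_conversions():
    assert percent_per_sd(0.052) == 5.3
    assert percent_per_sd(0.0) == 0.0
    assert percent_per_sd(0.081) == 8.4


# ---------------------------------------------------------------------------
# association models

def test_linear_exact_fit_flagged():
    prs = np.arange(10.0)
    res = linear_assoc(2 * prs, prs)
    assert res.beta == pytest.approx(2.0, abs=1e-12)
    assert res.note == "zero residual variance"


def test_linear_matches_normal_equations_oracle(rng):
    n = 10
    prs = rng.normal(0, 1, n)
    cov = rng.normal(0, 1, n)
    y = 0.7 * prs + 0.2 * cov + rng.normal(0, 1, n)
    x = np.column_stack([np.ones(n), prs, cov])
    bh = np.linalg.solve(x.T @ x, x.T @ y)
    resid = y - x @ bh
    s2 = resid @ resid / (n - 3)
    se = math.sqrt(s2 * np.linalg.inv(x.T @ x)[1, 1])
    from scipy import stats
    p = 2 * stats.t.sf(abs(bh[1] / se), n - 3)
    res = linear_assoc(y, prs, cov)
    assert res.beta == pytest.approx(bh[1], abs=1e-10)
    assert res.se == pytest.approx(se, abs=1e-10)
    assert res.p == pytest.approx(p, abs=1e-10)


def test_linear_collinearity_rejected(rng):
    prs = rng.normal(0, 1, 50)
    with pytest.raises(ValueError, match="collinear"):
        linear_assoc(rng.normal(0, 1, 50), prs, np.column_stack([prs, prs]))


def test_logistic_matches_2x2_closed_form():
    # exposed: 10/20 cases; unexposed: 5/20 cases -> OR = (10*15)/(10*5) = 3
    exposure = np.r_[np.ones(20), np.zeros(20)]
    y = np.r_[np.ones(10), np.zeros(10), np.ones(5), np.zeros(15)]
    res = logistic_assoc(y, exposure)
    assert res.beta == pytest.approx(math.log(3.0), abs=1e-8)
    se = math.sqrt(1 / 10 + 1 / 10 + 1 / 5 + 1 / 15)
    assert res.se == pytest.approx(se, abs=1e-6)
    assert res.odds_ratio == pytest.approx(3.0, abs=1e-6)


def test_logistic_null_and_separation(rng):
    y = rng.integers(0, 2, 500)
    res = logistic_assoc(y, rng.normal(0, 1, 500))
    assert abs(res.beta) < 3 * res.se
    with pytest.raises(RuntimeError):
        logistic_assoc(np.r_[np.zeros(20), np.ones(20)],
                       np.r_[np.zeros(20), np.ones(20)])
    with pytest.raises(ValueError):
        logistic_assoc(np.ones(20), rng.normal(0, 1, 20))


def test_meta_fixed_examples():
    one = meta_fixed([AssocResult(0.5, 0.1, 0.01, 100)])
    assert (one.beta, one.se) == (0.5, 0.1)
    assert one.q_stat == 0.0 and one.p_q == 1.0

    two = meta_fixed([AssocResult(1.0, 1.0, 0.5, 10),
                      AssocResult(3.0, 1.0, 0.5, 10)])
    assert two.beta == pytest.approx(2.0)
    assert two.se == pytest.approx(1 / math.sqrt(2))

    same = meta_fixed([AssocResult(0.7, s, 0.5, 10)
                       for s in (0.1, 0.5, 1.0, 2.0)])
    assert same.q_stat == pytest.approx(0.0, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.05, 3)),
                min_size=1, max_size=8))
def test_meta_fixed_properties(pairs):
    results = [AssocResult(b, s, 0.5, 10) for b, s in pairs]
    pooled = meta_fixed(results)
    assert pooled.se <= min(s for _, s in pairs) + 1e-12
    assert min(b for b, _ in pairs) - 1e-9 <= pooled.beta \
        <= max(b for b, _ in pairs) + 1e-9
    assert 0 < pooled.p_q <= 1


# ---------------------------------------------------------------------------
# discrimination

def test_auc_examples_and_brute_force():
    assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0
    assert auc(np.ones(10), np.r_[np.ones(5), np.zeros(5)]) == 0.5

    scores = np.array([0.9, 0.4, 0.5, 0.1])
    labels = np.array([1, 1, 0, 0])
    # brute force over all case-control pairs
    cases, ctrls = scores[labels == 1], scores[labels == 0]
    brute = np.mean([(c > d) + 0.5 * (c == d)
                     for c in cases for d in ctrls])
    assert auc(scores, labels) == pytest.approx(brute) == 0.75


def test_auc_monotone_invariance_and_sklearn_crosscheck(rng):
    scores = rng.normal(0, 1, 300)
    labels = rng.random(300) < 1 / (1 + np.exp(-scores))
    if labels.all() or not labels.any():
        pytest.skip("degenerate draw")
    a = auc(scores, labels)
    assert auc(np.exp(scores), labels) == pytest.approx(a, abs=1e-12)
    from sklearn.metrics import roc_auc_score
    assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


def test_delong_self_comparison_is_null(rng):
    scores = rng.normal(0, 1, 200)
    labels = rng.integers(0, 2, 200).astype(bool)
    delta, p = delong_test(scores, scores, labels)
    assert delta == 0.0 and p == 1.0


def test_delta_auc_planted_effect_detected(rng):
    n = 1500
    prs = rng.normal(0, 1, n)
    age = rng.normal(50, 10, n)
    eta = -1.0 + math.log(2.0) * prs + 0.02 * (age - 50)
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    res = delta_auc(y, prs, age.reshape(-1, 1), np.zeros((n, 0)))
    assert res.auc_m3 > res.auc_m1
    assert res.delta > 0
    assert res.p_delong < 0.01
    assert 0.5 < res.auc_m2 < 1.0


# ---------------------------------------------------------------------------
# diagnostics and quintile tests

def test_diagnostics_forced_arithmetic():
    # top 20 of 100 flagged: 15 diseased; remaining 80: 35 diseased
    prs = np.arange(100.0)
    disease = np.zeros(100, bool)
    disease[85:] = True          # 15 of the top 20
    disease[:35] = True          # 35 of the bottom 80
    d = diagnostics_top20(prs, disease)
    assert d.ppv == pytest.approx(0.75)
    assert d.npv == pytest.approx(0.5625)
    assert d.sensitivity == pytest.approx(0.30)
    assert d.specificity == pytest.approx(0.90)


def test_diagnostics_perfect_and_independent(rng):
    prs = np.arange(100.0)
    top_only = prs > 79
    d = diagnostics_top20(prs, top_only)
    assert d.ppv == 1.0 and d.sensitivity == 1.0

    n = 20_000
    prs = rng.normal(0, 1, n)
    disease = rng.random(n) < 0.3
    d = diagnostics_top20(prs, disease)
    assert d.ppv == pytest.approx(0.3, abs=0.03)  # PPV ~ prevalence


def test_diagnostics_identities(rng):
    prs = rng.normal(0, 1, 500)
    disease = rng.random(500) < 0.4
    d = diagnostics_top20(prs, disease)
    flagged = int((prs > np.quantile(prs, 0.8)).sum())
    cases = int(disease.sum())
    ctrls = 500 - cases
    assert d.sensitivity * cases + (1 - d.specificity) * ctrls \
        == pytest.approx(flagged)
    assert d.ppv * flagged == pytest.approx(d.sensitivity * cases)


def test_quintile_trend_and_tails(rng):
    n = 1000
    q = rng.integers(1, 6, n)
    flat = rng.normal(0, 1, n)
    trend, top, bottom = quintile_tests(flat, q)
    assert abs(trend.beta) < 3 * trend.se

    steep = 0.5 * q + rng.normal(0, 0.1, n)
    trend2, _, _ = quintile_tests(steep, q)
    assert trend2.p < 1e-6

    # the top-20% contrast is definitionally a fit on the derived flag
    direct = linear_assoc(flat, (q == 5).astype(float), model_id="top20")
    assert top.beta == pytest.approx(direct.beta, abs=1e-12)
    assert top.se == pytest.approx(direct.se, abs=1e-12)

    with pytest.raises(ValueError):
        quintile_tests(flat, np.where(q == 5, 4, q))


def test_quintile_logistic_trend(rng):
    n = 3000
    q = rng.integers(1, 6, n)
    eta = -1.0 + math.log(1.4) * (q - 3)
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    trend, top, bottom = quintile_tests(y, q, outcome_type="logistic")
    lo, hi = trend.or_ci()
    assert lo < 1.4 < hi
    assert top.odds_ratio > 1 and bottom.odds_ratio < 1
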