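"""End-to-end synthetic study: derive, select, and clinically evaluate a PRS.

Mirrors the design of a summary-statistics PRS study: a GWAS sample provides
marginal effects, an external reference panel provides LD, candidate scores
come from a 27-cell pruning-and-thresholding grid plus 7 point-normal
shrinkage settings, the winner is picked by pooled Fisher-Z correlation in
validation cohorts, and the winning score is evaluated against lipid levels,
dyslipidemia, longitudinal change, a cIMT-like outcome, and CHD case status
in independent cohorts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import clump, evaluate, qc, select, shrink, sim
from .io import GenotypePanel, SummaryStats, WeightSet

#: default cohort layout of the synthetic study (roles as in the source design:
#: four validation cohorts, a large reference/testing registry, a longitudinal
#: adolescent subset, an adult-women cIMT cohort, and a CHD case-control set)
DEFAULT_SPECS = [
    sim.CohortSpec("children", 500, "validation",
                   outcome_params={"age_group": "child"}),
    sim.CohortSpec("adolescents", 1000, "validation",
                   outcome_params={"age_group": "adolescent"}),
    sim.CohortSpec("adults", 500, "validation"),
    sim.CohortSpec("women", 500, "validation"),
    sim.CohortSpec("registry", 2000, "reference-quintile"),
    sim.CohortSpec("t2d_biobank", 800, "testing"),
    sim.CohortSpec("followup", 600, "longitudinal"),
    sim.CohortSpec("cimt_women", 800, "cimt"),
    sim.CohortSpec("t2d_chd", 2000, "chd",
                   outcome_params={"log_or_per_sd": math.log(1.3),
                                   "prevalence": 0.275}),
]

PC_COLS = ["pc1", "pc2", "pc3", "pc4"]


@dataclass
class StudyResult:
    config: sim.SimulationConfig
    arch: sim.TrueArchitecture
    candidates: list[WeightSet]
    selection: "select.SelectionTable"
    cohorts: dict[str, sim.CohortTable]
    metrics: dict = field(default_factory=dict)

    @property
    def best(self) -> WeightSet:
        return self.candidates[self.selection.best_index]


def derive_candidates(ss: SummaryStats, panel: GenotypePanel,
                      h2: float | None = None, seed: int = 0,
                      n_iter: int = 100, burn_in: int = 10,
                      ld_radius: int | None = None) -> list[WeightSet]:
    """All 34 candidate weight sets: 27 pruning-and-thresholding cells
    followed by 7 shrinkage settings (rho grid)."""
    cands = clump.grid_candidates(ss, panel)
    m = len(ss)
    if ld_radius is None:
        ld_radius = shrink.default_ld_radius(m)
    ld = shrink.build_ld_windows(panel, ld_radius)
    if h2 is None:
        h2 = shrink.estimate_h2_aggregate(ss, ld)
    cfg = shrink.ShrinkConfig(rho=1.0, h2=h2, n_gwas=int(ss.table["n"].mean()),
                              m=m, ld_radius=ld_radius, n_iter=n_iter,
                              burn_in=burn_in, seed=seed)
    cands.extend(shrink.grid_candidates_bayes(ss, panel, cfg))
    return cands


def run_study(seed: int = 0, config: sim.SimulationConfig | None = None,
              specs: list[sim.CohortSpec] | None = None,
              trait: str = "tc") -> StudyResult:
    """Simulate, derive, select, and evaluate; returns all artifacts plus a
    flat metrics dict (see the acceptance script for the full key list)."""
    config = config or sim.SimulationConfig(seed=seed)
    specs = specs if specs is not None else DEFAULT_SPECS
    refs = [s for s in specs if s.role == "reference-quintile"]
    if len(refs) != 1:
        raise sim.ConfigurationError(
            "exactly one cohort must carry role reference-quintile")

    panel = sim.simulate_reference_panel(config)
    arch = sim.simulate_architecture(config, panel)
    ss = sim.simulate_gwas_summary(panel, arch, config)
    ss, _ = qc.harmonize(ss, panel)

    candidates = derive_candidates(ss, panel, seed=config.seed)
    cohorts = {c.label: c for c in sim.simulate_cohorts(config, arch, specs)}
    validation = [c for c in cohorts.values() if c.role == "validation"]
    selection = select.select_best(candidates, validation, trait=trait)
    best = candidates[selection.best_index]

    result = StudyResult(config, arch, candidates, selection, cohorts)
    result.metrics = _evaluate_best(best, cohorts, refs[0].label, trait)
    result.metrics["pooled_r_validation"] = float(
        selection.table.loc[0, "pooled_r"])
    result.metrics["best_method"] = selection.table.loc[0, "method"]
    result.metrics["best_n_variants"] = int(
        selection.table.loc[0, "n_variants"])
    return result


def _evaluate_best(best: WeightSet, cohorts: dict, ref_label: str,
                   trait: str) -> dict:
    m: dict = {}
    ref_prs = clump.score(cohorts[ref_label].panel, best)
    dys_col = f"dys_{trait}"

    def covars(df):
        return np.column_stack(
            [df["sex"], df["age"], df["bmi"], df[PC_COLS]])

    # lipid-level associations, pooled across testing-stage cohorts
    assoc, corrs = [], []
    for c in cohorts.values():
        if c.role not in ("testing", "reference-quintile"):
            continue
        prs = clump.score(c.panel, best)
        std = select.standardize_and_quintile(prs, ref_prs)
        y = np.log(c.table[trait].to_numpy(float))
        assoc.append(evaluate.linear_assoc(
            y, std.z_value, covars(c.table), model_id=c.label))
        corrs.append(select.cohort_correlations(prs, y, c.label))
        if c.role == "reference-quintile":
            m["delta_r2_registry"] = select.variance_explained(
                y, std.z_value, covars(c.table))
    meta = evaluate.meta_fixed(assoc)
    m["beta_per_sd_testing"] = meta.beta
    m["pct_per_sd_testing"] = evaluate.percent_per_sd(meta.beta)
    m["pooled_r_testing"] = select.pool_fisher(corrs)

    # discrimination and diagnostics for dyslipidemia in the registry
    reg = cohorts[ref_label]
    std = select.standardize_and_quintile(ref_prs, ref_prs)
    labels = reg.table[dys_col].to_numpy(bool)
    da = evaluate.delta_auc(labels, std.z_value,
                            reg.table[["sex", "age", "bmi"]].to_numpy(float),
                            reg.table[PC_COLS].to_numpy(float))
    m.update(auc_clinical=da.auc_m1, auc_prs_only=da.auc_m2,
             auc_full=da.auc_m3, delta_auc=da.delta,
             p_delong=da.p_delong)
    diag = evaluate.diagnostics_top20(std.z_value, labels)
    m.update(ppv_top20=diag.ppv, npv_top20=diag.npv,
             sens_top20=diag.sensitivity, spec_top20=diag.specificity)

    # 3-year change in the longitudinal cohort
    for c in cohorts.values():
        if c.role != "longitudinal":
            continue
        prs = clump.score(c.panel, best)
        std = select.standardize_and_quintile(prs, ref_prs)
        base = c.table[trait].to_numpy(float)
        fu = c.table[f"{trait}_fu"].to_numpy(float)
        change = evaluate.relative_change(base, fu)
        cov = np.column_stack([covars(c.table), np.log(base)])
        res = evaluate.linear_assoc(change, std.z_value, cov,
                                    model_id="3y-change")
        m["beta_change_3y"] = res.beta
        m["p_change_3y"] = res.p

    # cIMT quintile trend in the cimt cohort
    for c in cohorts.values():
        if c.role != "cimt":
            continue
        prs = clump.score(c.panel, best)
        std = select.standardize_and_quintile(prs, ref_prs)
        cov = np.column_stack([c.table["age"], c.table[PC_COLS]])
        trend, top, _ = evaluate.quintile_tests(
            np.log(c.table["cimt"].to_numpy(float)), std.quintile, cov,
            outcome_type="linear")
        m["beta_cimt_trend"] = trend.beta
        m["p_cimt_trend"] = trend.p

    # CHD quintile analyses in the case-control cohort
    for c in cohorts.values():
        if c.role != "chd":
            continue
        prs = clump.score(c.panel, best)
        std = select.standardize_and_quintile(prs, ref_prs)
        cov = np.column_stack([
            c.table["sex"], c.table["age"], c.table["duration_dm"],
            c.table["bmi"], c.table["smoking"], c.table["hba1c"],
            c.table["sbp"], c.table["egfr"], c.table["ln_acr"],
            c.table[PC_COLS]])
        y = c.table["chd"].to_numpy(bool)
        trend, top, bottom = evaluate.quintile_tests(
            y, std.quintile, cov, outcome_type="logistic")
        m["or_chd_per_quintile"] = trend.odds_ratio
        m["p_chd_trend"] = trend.p
        m["or_chd_top20"] = top.odds_ratio
        m["p_chd_top20"] = top.p
        res_sd = evaluate.logistic_assoc(y, std.z_value, cov, "per-sd")
        m["or_chd_per_sd"] = res_sd.odds_ratio
    return m
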