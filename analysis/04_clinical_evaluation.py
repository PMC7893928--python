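#!/usr/bin/env python
"""Stage 4 — clinical evaluation of the selected score.

Standardizes the winning score with the registry cohort's mean/SD and
quintile cuts, then reports: per-SD lipid association and incremental R2 in
the registry, dyslipidemia discrimination (AUC of clinical factors vs
clinical factors + PRS, DeLong p), top-20% diagnostics, the 3-year lipid
change association, the cIMT quintile trend, and CHD quintile odds ratios.
Writes a tidy metrics table under results/.
"""
import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lipidprs import clump, evaluate as ev, io, select
from lipidprs.pipeline import PC_COLS

TRAIT = "tc"


def _load(simdir: Path, label: str):
    panel = io.read_vcf(simdir / f"cohort_{label}.vcf")
    table = pd.read_csv(simdir / f"cohort_{label}.csv")
    return panel, table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--best", type=Path,
                    default=Path("results/best/best_score.txt"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    best = io.read_weights(args.best)
    metrics: dict[str, float] = {}

    reg_panel, reg = _load(args.sim, "registry")
    ref_prs = clump.score(reg_panel, best)
    std = select.standardize_and_quintile(ref_prs, ref_prs)
    y = np.log(reg[TRAIT].to_numpy())
    covars = np.column_stack([reg["sex"], reg["age"], reg["bmi"],
                              reg[PC_COLS]])
    res = ev.linear_assoc(y, std.z_value, covars, model_id="registry")
    metrics["beta_per_sd"] = res.beta
    metrics["pct_per_sd"] = ev.percent_per_sd(res.beta)
    metrics["delta_r2"] = select.variance_explained(y, std.z_value, covars)
    print(f"registry (n={len(reg)}): beta/SD = {res.beta:.3f} "
          f"({metrics['pct_per_sd']}% per SD), dR2 = "
          f"{metrics['delta_r2']:.3f}, p = {res.p:.2e}")

    labels = reg[f"dys_{TRAIT}"].to_numpy(bool)
    da = ev.delta_auc(labels, std.z_value,
                      reg[["sex", "age", "bmi"]].to_numpy(float),
                      reg[PC_COLS].to_numpy(float))
    diag = ev.diagnostics_top20(std.z_value, labels)
    metrics.update(auc_clinical=da.auc_m1, auc_prs=da.auc_m2,
                   auc_full=da.auc_m3, delta_auc=da.delta,
                   p_delong=da.p_delong, ppv=diag.ppv, npv=diag.npv,
                   sensitivity=diag.sensitivity, specificity=diag.specificity)
    print(f"dyslipidemia AUC: clinical {da.auc_m1:.3f} -> +PRS "
          f"{da.auc_m3:.3f} (delta {da.delta:.3f}, DeLong p "
          f"{da.p_delong:.2e}); top-20% PPV {diag.ppv:.2f} NPV {diag.npv:.2f}")

    fu_panel, fu = _load(args.sim, "followup")
    prs = clump.score(fu_panel, best)
    z = select.standardize_and_quintile(prs, ref_prs).z_value
    change = ev.relative_change(fu[TRAIT].to_numpy(),
                                fu[f"{TRAIT}_fu"].to_numpy())
    cov = np.column_stack([fu["sex"], fu["age"], fu["bmi"], fu[PC_COLS],
                           np.log(fu[TRAIT].to_numpy())])
    res_fu = ev.linear_assoc(change, z, cov, model_id="3y-change")
    metrics["beta_change_3y"] = res_fu.beta
    metrics["p_change_3y"] = res_fu.p
    print(f"3-year change (n={len(fu)}): beta/SD = {res_fu.beta:.4f}, "
          f"p = {res_fu.p:.2e}")

    ci_panel, ci = _load(args.sim, "cimt_women")
    q = select.standardize_and_quintile(clump.score(ci_panel, best),
                                        ref_prs).quintile
    cov = np.column_stack([ci["age"], ci[PC_COLS]])
    trend, top, _ = ev.quintile_tests(np.log(ci["cimt"].to_numpy()), q, cov)
    metrics["beta_cimt_trend"] = trend.beta
    metrics["p_cimt_trend"] = trend.p
    print(f"cIMT (n={len(ci)}): trend beta = {trend.beta:.4f}/quintile, "
          f"p = {trend.p:.3f}")

    chd_panel, chd = _load(args.sim, "t2d_chd")
    stdc = select.standardize_and_quintile(clump.score(chd_panel, best),
                                           ref_prs)
    cov = np.column_stack([chd["sex"], chd["age"], chd["duration_dm"],
                           chd["bmi"], chd["smoking"], chd["hba1c"],
                           chd["sbp"], chd["egfr"], chd["ln_acr"],
                           chd[PC_COLS]])
    yc = chd["chd"].to_numpy(bool)
    trend, top, bottom = ev.quintile_tests(yc, stdc.quintile, cov,
                                           outcome_type="logistic")
    lo, hi = trend.or_ci()
    metrics.update(or_chd_per_quintile=trend.odds_ratio,
                   or_chd_ci_low=lo, or_chd_ci_high=hi,
                   p_chd_trend=trend.p, or_chd_top20=top.odds_ratio)
    print(f"CHD in T2D (n={len(chd)}, {int(yc.sum())} cases): OR/quintile = "
          f"{trend.odds_ratio:.3f} ({lo:.3f}-{hi:.3f}), p = {trend.p:.3f}; "
          f"top-20% OR = {top.odds_ratio:.3f}")

    out_path = args.out / "clinical_metrics.json"
    out_path.write_text(json.dumps(metrics, indent=2) + "\n")
    pd.Series(metrics).rename("value").to_csv(args.out /
                                              "clinical_metrics.csv")
    print(f"metrics written to {out_path}")


if __name__ == "__main__":
    main()
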