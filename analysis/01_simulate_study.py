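#!/usr/bin/env python
"""Stage 1 — build the synthetic study inputs.

Generates an LD reference panel, a marginal GWAS on a fresh sample, and the
multi-cohort validation/testing/outcome tables, all with known ground truth,
and writes them as VCF / TSV / CSV under results/sim/ for the later stages.
The demo scale (800 variants, cohorts of a few hundred) keeps the whole
analysis chain at about a minute; the acceptance script runs the full
default conditions instead.
"""
import argparse
import math
from pathlib import Path

from lipidprs import io, sim

SPECS = [
    sim.CohortSpec("children", 300, "validation",
                   outcome_params={"age_group": "child"}),
    sim.CohortSpec("adolescents", 500, "validation",
                   outcome_params={"age_group": "adolescent"}),
    sim.CohortSpec("women", 300, "validation"),
    sim.CohortSpec("registry", 800, "reference-quintile"),
    sim.CohortSpec("followup", 300, "longitudinal"),
    sim.CohortSpec("cimt_women", 400, "cimt"),
    sim.CohortSpec("t2d_chd", 800, "chd",
                   outcome_params={"log_or_per_sd": math.log(1.3),
                                   "prevalence": 0.275}),
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = sim.SimulationConfig(n_ref=400, n_gwas=8000, m_variants=800,
                                  seed=args.seed)
    panel = sim.simulate_reference_panel(config)
    arch = sim.simulate_architecture(config, panel)
    ss = sim.simulate_gwas_summary(panel, arch, config)

    io.write_vcf(panel, args.out / "reference.vcf")
    io.write_summary_stats(ss, args.out / "gwas_sumstats.tsv")
    sim.write_architecture(arch, panel, args.out / "architecture_truth.tsv")
    cohorts = sim.simulate_cohorts(config, arch, SPECS)
    for cohort in cohorts:
        io.write_vcf(cohort.panel, args.out / f"cohort_{cohort.label}.vcf")
        sim.write_cohort_csv(cohort, args.out / f"cohort_{cohort.label}.csv")

    n_causal = int(arch.causal_mask.sum())
    gws = int((ss.table["p"] < 5e-8).sum())
    print(f"simulated {config.m_variants} variants on "
          f"{panel.variants['chrom'].nunique()} chromosomes; "
          f"{n_causal} causal (rho_true={config.p_causal}, h2={config.h2})")
    print(f"GWAS at N={config.n_gwas}: {gws} variants reach genome-wide "
          f"significance (p < 5e-8)")
    print(f"wrote reference panel + {len(cohorts)} cohorts to {args.out}")


if __name__ == "__main__":
    main()
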