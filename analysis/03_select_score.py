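#!/usr/bin/env python
"""Stage 3 — validate all candidates and select the best score.

Scores every candidate in every validation cohort, pools per-cohort Pearson
correlations with ln(TC) on the Fisher-Z scale (weights n-3), and flags the
candidate with the maximal pooled correlation.  Writes the full ranking
table and copies the winning scoring file to results/best/.
"""
import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lipidprs import io, select, sim


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--candidates", type=Path,
                    default=Path("results/candidates"))
    ap.add_argument("--trait", default="tc")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    manifest = json.loads((args.candidates / "manifest.json").read_text())
    cands = [io.read_weights(args.candidates / m["file"]) for m in manifest]

    cohorts = []
    for csv_path in sorted(args.sim.glob("cohort_*.csv")):
        label = csv_path.stem.removeprefix("cohort_")
        if label not in ("children", "adolescents", "women"):
            continue
        panel = io.read_vcf(args.sim / f"cohort_{label}.vcf")
        table = pd.read_csv(csv_path)
        cohorts.append(sim.CohortTable(label, "validation", table, panel,
                                       np.zeros(len(table))))

    selection = select.select_best(cands, cohorts, trait=args.trait)
    selection.table.to_csv(args.out / "selection.csv", index=False)
    best = cands[selection.best_index]
    (args.out / "best").mkdir(parents=True, exist_ok=True)
    io.write_weights(best, args.out / "best" / "best_score.txt")

    top = selection.table.iloc[0]
    print(f"validated {len(cands)} candidates in {len(cohorts)} cohorts "
          f"(n = {sum(len(c.table) for c in cohorts)})")
    print(f"best: {top['method']} candidate #{int(top['candidate'])} "
          f"({int(top['n_variants'])} variants), pooled r = "
          f"{top['pooled_r']:.3f} with ln({args.trait.upper()})")
    print(selection.table.head(5)[
        ["rank", "method", "n_variants", "pooled_r"]].to_string(index=False))
    print(f"ranking written to {args.out/'selection.csv'}; winner copied to "
          f"{args.out/'best'}")


if __name__ == "__main__":
    main()
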