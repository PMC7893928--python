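#!/usr/bin/env python
"""Stage 2 — derive the 34 candidate scores.

Reads the GWAS summary statistics and reference VCF from stage 1, harmonizes
alleles, then derives 27 pruning-and-thresholding candidates (p in
{1 ... 5e-8} x r2 in {0.2, 0.4, 0.6}, 250 kb windows) and 7 point-normal
shrinkage candidates (rho grid, aggregate-chi2 heritability).  Writes one
PGS-style scoring file per candidate plus a provenance manifest.
"""
import argparse
import json
from pathlib import Path

from lipidprs import io, pipeline, qc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--sim", type=Path, default=Path("results/sim"))
    ap.add_argument("--out", type=Path, default=Path("results/candidates"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    panel = io.read_vcf(args.sim / "reference.vcf")
    ss = io.read_summary_stats(args.sim / "gwas_sumstats.tsv")
    ss, report = qc.harmonize(ss, panel)
    print(f"harmonized {report.n_retained}/{report.n_input} summary rows "
          f"(removed: {report.stages})")

    cands = pipeline.derive_candidates(ss, panel, seed=args.seed)
    manifest = []
    for i, ws in enumerate(cands):
        name = f"candidate_{i:02d}.txt"
        io.write_weights(ws, args.out / name)
        manifest.append({"file": name, **ws.provenance})
    (args.out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    pt = [m for m in manifest if m["method"] == "pt"]
    bayes = [m for m in manifest if m["method"] == "bayes"]
    sizes = sorted(m["n_variants"] for m in pt)
    print(f"derived {len(pt)} pruning-and-thresholding candidates "
          f"({sizes[0]}-{sizes[-1]} variants) and {len(bayes)} shrinkage "
          f"candidates (h2 input {bayes[0]['h2']:.3f})")
    print(f"wrote {len(manifest)} scoring files to {args.out}")


if __name__ == "__main__":
    main()
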