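"""Readers/writers and in-memory containers for the formats the pipeline touches.

Genotypes travel as a dense dosage matrix (samples x variants, effect-allele
copies in [0, 2], NaN for missing) with a variant table alongside; GWAS summary
statistics and PRS weight sets are pandas DataFrames with fixed schemas.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: required columns of a variant table
VARIANT_COLS = ["chrom", "pos", "id", "ea", "nea"]
#: required columns of a summary-statistics table
SUMSTAT_COLS = ["chrom", "pos", "id", "ea", "nea", "beta", "se", "p", "n"]
#: column order of a PGS-Catalog-style scoring file
SCORING_COLS = [
    "rsID", "chr_name", "chr_position", "effect_allele", "other_allele",
    "effect_weight",
]

VALID_ALLELES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class GenotypePanel:
    """Individuals x variants dosage matrix plus variant metadata.

    ``dosages[i, k]`` counts copies of the effect allele ``variants.ea[k]``
    carried by sample ``samples[i]``; NaN marks a missing genotype.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def eaf(self) -> np.ndarray:
        """Empirical effect-allele frequency from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_variants(self, mask_or_idx) -> "GenotypePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        variants = self.variants.iloc[idx].reset_index(drop=True)
        return GenotypePanel(self.samples, variants, self.dosages[:, idx])

    def subset_samples(self, mask_or_idx) -> "GenotypePanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        samples = [self.samples[i] for i in idx]
        return GenotypePanel(samples, self.variants.copy(), self.dosages[idx])


@dataclass
class SummaryStats:
    """Per-variant marginal GWAS effects (beta-hat, SE, p, N) on the ln scale."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTAT_COLS if c not in self.table.columns]
        if missing:
            raise FormatError(f"summary statistics missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class WeightSet:
    """A derived PRS model: variants, effect alleles, per-allele weights.

    ``provenance`` records the deriving method and its tuning parameters,
    e.g. ``{"method": "pt", "p_threshold": 1e-5, "r2_threshold": 0.2}``.
    """

    variants: pd.DataFrame
    weights: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.variants):
            raise ValueError("weights and variants length mismatch")
        key = self.variants[["chrom", "pos"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError("duplicate chrom:pos in weight set")
        if len(self.weights) and not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite weights")

    def __len__(self) -> int:
        return len(self.weights)


def _clean_chrom(values) -> pd.Series:
    return pd.Series(values).astype(str).str.replace("^chr", "", regex=True)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path) -> GenotypePanel:
    """Read genotypes from a VCF into a :class:`GenotypePanel`.

    Per-sample DS (imputed dosage) is preferred when present, otherwise the
    GT alternate-allele count is used; ``./.`` becomes NaN.  Multi-allelic and
    non-SNP records are skipped with a logged count.  Dosages count copies of
    the ALT allele, which is stored as the panel's effect allele.
    """
    from cyvcf2 import VCF

    path = str(path)
    _validate_vcf_text(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib reports its own diagnostics
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    n_skipped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        try:
            ds = var.format("DS")
        except KeyError:  # DS absent from the header
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col[col < 0] = np.nan  # htslib missing sentinel
        else:
            col = np.empty(len(samples))
            for i, gt in enumerate(var.genotypes):
                a = [x for x in gt[:-1] if x >= 0]
                col[i] = sum(1 for x in a if x > 0) if len(a) == 2 else np.nan
        rows.append((str(var.CHROM).removeprefix("chr"), var.POS,
                     var.ID or f"{var.CHROM}:{var.POS}", alts[0], var.REF))
        dosage_cols.append(col)
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    variants = pd.DataFrame(rows, columns=VARIANT_COLS)
    dosages = (np.column_stack(dosage_cols) if dosage_cols
               else np.empty((len(samples), 0)))
    panel = GenotypePanel(samples, variants, dosages)
    panel.variants["eaf"] = panel.eaf()
    return panel


def _validate_vcf_text(path: str) -> None:
    """Cheap structural pre-check so parse errors can name a line number."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCF"):
            raise FormatError(f"{path}: line 1: missing ##fileformat header")
        for lineno, line in enumerate(fh, start=2):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                return
            raise FormatError(
                f"{path}: line {lineno}: expected #CHROM header before records"
            )
    raise FormatError(f"{path}: no #CHROM header line found")


def write_vcf(panel: GenotypePanel, path, write_ds: bool = False) -> None:
    """Write a panel as VCF v4.2 with GT (and optionally DS) fields.

    Integral dosages are emitted as unphased GT; non-integral or missing
    dosages force a DS field regardless of ``write_ds``.
    """
    v = panel.variants
    need_ds = write_ds or bool(np.any(~np.isnan(panel.dosages) &
                                      (panel.dosages % 1 != 0)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if need_ds:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Effect allele dosage">\n')
        for chrom in pd.unique(v["chrom"]):
            maxpos = int(v.loc[v["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        fmt = "GT:DS" if need_ds else "GT"
        for k in range(panel.n_variants):
            row = v.iloc[k]
            fields = [str(row.chrom), str(int(row.pos)), str(row.id),
                      str(row.nea), str(row.ea), ".", "PASS", ".", fmt]
            for d in panel.dosages[:, k]:
                if np.isnan(d):
                    gt = "./."
                    cell = f"{gt}:." if need_ds else gt
                else:
                    g = int(round(d))
                    g = min(max(g, 0), 2)
                    gt = ["0/0", "0/1", "1/1"][g]
                    cell = f"{gt}:{d:g}" if need_ds else gt
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# summary statistics

#: accepted header aliases for summary-statistic columns
_SS_ALIASES = {
    "chrom": ["CHR", "chrom", "chromosome", "chr_name"],
    "pos": ["POS", "pos", "position", "chr_position"],
    "id": ["ID", "id", "rsID", "SNP"],
    "ea": ["EA", "ea", "effect_allele", "A1"],
    "nea": ["NEA", "nea", "other_allele", "A2"],
    "beta": ["BETA", "beta"],
    "se": ["SE", "se"],
    "p": ["P", "p", "pval", "p_value"],
    "n": ["N", "n"],
}


def read_summary_stats(path) -> SummaryStats:
    """Read tab-delimited GWAS summary statistics.

    Rows with missing/invalid beta, SE (must be > 0) or p (must lie in (0, 1])
    are dropped with a logged count; alleles are upper-cased.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    colmap = {}
    for canon, aliases in _SS_ALIASES.items():
        hit = next((a for a in aliases if a in raw.columns), None)
        if hit is not None:
            colmap[hit] = canon
    missing = [c for c in SUMSTAT_COLS if c not in colmap.values()]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df = raw.rename(columns=colmap)[SUMSTAT_COLS].copy()
    df["chrom"] = _clean_chrom(df["chrom"])
    df["ea"] = df["ea"].str.upper()
    df["nea"] = df["nea"].str.upper()
    for c in ("beta", "se", "p"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = (df["beta"].notna() & df["se"].notna() & (df["se"] > 0)
          & df["p"].notna() & (df["p"] > 0) & (df["p"] <= 1))
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("read_summary_stats: dropped %d invalid rows", n_dropped)
    return SummaryStats(df[ok].reset_index(drop=True))


def write_summary_stats(ss: SummaryStats, path) -> None:
    out = ss.table.rename(columns={
        "chrom": "CHR", "pos": "POS", "id": "ID", "ea": "EA", "nea": "NEA",
        "beta": "BETA", "se": "SE", "p": "P", "n": "N"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PGS-Catalog-style scoring files

def write_weights(ws: WeightSet, path) -> None:
    """Write a weight set in PGS Catalog scoring format (tab-delimited).

    Weights are serialized at 17 significant digits so the decimal text
    round-trips the float64 exactly.
    """
    with open(path, "w") as fh:
        for key, val in sorted(ws.provenance.items()):
            fh.write(f"#{key}={val}\n")
        fh.write("\t".join(SCORING_COLS) + "\n")
        for k in range(len(ws)):
            row = ws.variants.iloc[k]
            fh.write(f"{row.id}\t{row.chrom}\t{int(row.pos)}\t{row.ea}\t"
                     f"{row.nea}\t{ws.weights[k]:.17g}\n")


def read_weights(path) -> WeightSet:
    """Read a PGS Catalog scoring file written by :func:`write_weights`."""
    provenance = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].rstrip("\n").partition("=")
                provenance[key] = _maybe_number(val)
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", dtype={"chr_name": str},
                         float_precision="round_trip")
    missing = [c for c in SCORING_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: scoring file missing columns {missing}")
    if df["rsID"].duplicated().any():
        dupes = df.loc[df["rsID"].duplicated(), "rsID"].tolist()
        raise FormatError(f"{path}: duplicate variant IDs {dupes[:5]}")
    variants = pd.DataFrame({
        "chrom": _clean_chrom(df["chr_name"]),
        "pos": df["chr_position"].astype(int),
        "id": df["rsID"].astype(str),
        "ea": df["effect_allele"].astype(str).str.upper(),
        "nea": df["other_allele"].astype(str).str.upper(),
    })
    return WeightSet(variants, df["effect_weight"].to_numpy(float), provenance)


def _maybe_number(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text
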