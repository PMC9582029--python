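"""Readers and writers for the plain-text formats shared by all stages.

Every TSV written here starts with a ``# dialect:`` header comment naming
the table kind; readers validate it when present.  Coordinates are 1-based
inclusive throughout; the genome-build label is carried as opaque metadata.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from skinmgwas.datatypes import (
    AbundanceTable,
    GenotypeMatrix,
    SUMMARY_STAT_COLUMNS,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not satisfy its declared table contract."""


def _write_tsv(frame: pd.DataFrame, path: Path | str, dialect: str, index: bool) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# dialect: {dialect}\n")
        frame.to_csv(fh, sep="\t", index=index)


def _read_tsv(path: Path | str, dialect: str | None, index_col=None) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("# dialect:"):
        declared = first.split(":", 1)[1].strip()
        if dialect is not None and declared != dialect:
            raise FormatError(f"{path}: dialect {declared!r}, expected {dialect!r}")
        skip = 1
    return pd.read_csv(path, sep="\t", skiprows=skip, index_col=index_col)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def write_summary_stats(frame: pd.DataFrame, path: Path | str) -> None:
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"summary stats missing required column(s): {missing}")
    _write_tsv(frame, path, "summary_stats", index=False)


def read_summary_stats(path: Path | str) -> pd.DataFrame:
    """Typed summary-statistics table; malformed rows are rejected with
    their (1-based) line numbers logged."""
    frame = _read_tsv(path, "summary_stats")
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    frame["CHR"] = frame["CHR"].astype(str)
    for col in ("EAF", "BETA", "SE", "P"):
        frame[col] = pd.to_numeric(frame[col], errors="coerce")
    bad = (
        frame["SE"].isna()
        | (frame["SE"] <= 0)
        | frame["BETA"].isna()
        | frame["P"].isna()
        | (frame["P"] < 0)
        | (frame["P"] > 1)
    )
    if bad.any():
        # +2 accounts for the dialect comment and header lines
        lines = [int(i) + 3 for i in np.flatnonzero(bad.to_numpy())]
        logger.warning("%s: rejected %d malformed row(s) at line(s) %s",
                       path, int(bad.sum()), lines)
        frame = frame[~bad]
    frame["POS"] = frame["POS"].astype(np.int64)
    frame["N"] = frame["N"].astype(np.int64)
    return frame.reset_index(drop=True)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_dosage_tsv(g: GenotypeMatrix, prefix: Path | str) -> tuple[Path, Path]:
    """Write ``<prefix>.dosage.tsv`` (samples x variants) and
    ``<prefix>.variants.tsv`` (variant metadata)."""
    prefix = Path(prefix)
    dosage_path = prefix.with_suffix(".dosage.tsv")
    var_path = prefix.with_suffix(".variants.tsv")
    _write_tsv(g.dosages, dosage_path, "dosage", index=True)
    meta = g.variants.copy()
    _write_tsv(meta, var_path, "variant_meta", index=True)
    return dosage_path, var_path


def read_dosage_tsv(dosage_path: Path | str, variants_path: Path | str,
                    cohort: str | None = None) -> GenotypeMatrix:
    dosages = _read_tsv(dosage_path, "dosage", index_col=0)
    variants = _read_tsv(variants_path, "variant_meta", index_col=0)
    variants["chrom"] = variants["chrom"].astype(str)
    cohort_s = pd.Series(cohort, index=dosages.index) if cohort else None
    return GenotypeMatrix(dosages=dosages, variants=variants, cohort=cohort_s)


def write_vcf(g: GenotypeMatrix, path: Path | str) -> None:
    """Minimal VCF v4.2 with GT fields only.

    Dosage 0 -> 0/0, 1 -> 0/1, 2 -> 1/1, NaN -> ./. ; REF is the other
    allele and ALT the effect allele, so the ALT dosage equals the stored
    effect-allele dosage.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = list(g.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        dos = g.dosages.to_numpy(dtype=float)
        for j, (snp, meta) in enumerate(g.variants.iterrows()):
            calls = [
                "./." if np.isnan(v) else gt_map[int(round(v))] for v in dos[:, j]
            ]
            fh.write(
                f"{meta['chrom']}\t{int(meta['pos'])}\t{snp}\t{meta['oa']}\t"
                f"{meta['ea']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: Path | str, cohort: str | None = None) -> GenotypeMatrix:
    """Read a GT-only VCF back into a dosage matrix (effect allele = ALT)."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - exercised only without cyvcf2
        return _read_vcf_text(path, cohort)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snps, rows, meta = [], [], []
    for var in vcf:
        gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        dos = np.where(gts == 3, 2.0, gts)
        dos[gts == 2] = np.nan
        snps.append(var.ID)
        rows.append(dos)
        meta.append({"chrom": str(var.CHROM), "pos": int(var.POS),
                     "ea": var.ALT[0], "oa": var.REF})
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=snps)
    variants = pd.DataFrame(meta, index=pd.Index(snps, name="snp"))
    variants["eaf"] = dosages.mean(axis=0).to_numpy() / 2.0
    cohort_s = pd.Series(cohort, index=samples) if cohort else None
    return GenotypeMatrix(dosages=dosages, variants=variants, cohort=cohort_s)


def _read_vcf_text(path: Path | str, cohort: str | None = None) -> GenotypeMatrix:
    gt_dos = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0, "./.": np.nan,
              "0|0": 0.0, "0|1": 1.0, "1|0": 1.0, "1|1": 2.0, ".|.": np.nan}
    samples: list[str] = []
    snps, rows, meta = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            chrom, pos, snp, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            calls = [c.split(":")[0] for c in parts[9:]]
            rows.append([gt_dos.get(c, np.nan) for c in calls])
            snps.append(snp)
            meta.append({"chrom": chrom, "pos": int(pos), "ea": alt, "oa": ref})
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=snps)
    variants = pd.DataFrame(meta, index=pd.Index(snps, name="snp"))
    variants["eaf"] = dosages.mean(axis=0).to_numpy() / 2.0
    cohort_s = pd.Series(cohort, index=samples) if cohort else None
    return GenotypeMatrix(dosages=dosages, variants=variants, cohort=cohort_s)


# ---------------------------------------------------------------------------
# abundance tables / covariates / matrices
# ---------------------------------------------------------------------------

def write_abundance(table: AbundanceTable, prefix: Path | str) -> None:
    prefix = Path(prefix)
    _write_tsv(table.counts, prefix.with_suffix(".counts.tsv"), "counts", index=True)
    if table.taxonomy is not None:
        _write_tsv(table.taxonomy, prefix.with_suffix(".taxonomy.tsv"), "taxonomy", index=True)
    if table.sample_meta is not None:
        _write_tsv(table.sample_meta, prefix.with_suffix(".samples.tsv"), "sample_meta", index=True)


def read_abundance(prefix: Path | str) -> AbundanceTable:
    prefix = Path(prefix)
    counts = _read_tsv(prefix.with_suffix(".counts.tsv"), "counts", index_col=0)
    tax_path = prefix.with_suffix(".taxonomy.tsv")
    meta_path = prefix.with_suffix(".samples.tsv")
    taxonomy = _read_tsv(tax_path, "taxonomy", index_col=0) if tax_path.exists() else None
    meta = _read_tsv(meta_path, "sample_meta", index_col=0) if meta_path.exists() else None
    return AbundanceTable(counts=counts, taxonomy=taxonomy, sample_meta=meta)


def write_covariates(frame: pd.DataFrame, path: Path | str) -> None:
    _write_tsv(frame, path, "covariates", index=True)


def read_covariates(path: Path | str) -> pd.DataFrame:
    return _read_tsv(path, "covariates", index_col=0)


def write_matrix(frame: pd.DataFrame, path: Path | str, dialect: str = "matrix") -> None:
    _write_tsv(frame, path, dialect, index=True)


def read_matrix(path: Path | str, dialect: str = "matrix") -> pd.DataFrame:
    return _read_tsv(path, dialect, index_col=0)


def write_table(frame: pd.DataFrame, path: Path | str, dialect: str = "table") -> None:
    _write_tsv(frame, path, dialect, index=False)


def read_table(path: Path | str, dialect: str = "table") -> pd.DataFrame:
    return _read_tsv(path, dialect)
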