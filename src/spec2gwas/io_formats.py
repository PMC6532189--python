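"""Readers and writers for the external formats the pipeline touches.

Covers wide-format spectra tables (CSV with a wavelength header), phenotype
tables, VCF genotypes (via cyvcf2), gene models (GFF3 or BED), FASTQ read
records with the stated quality filters, and the tabular GWAS outputs.

All readers reject malformed input rather than silently coercing it, and
positions are 1-based inclusive throughout (VCF/GFF convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .spectra_preprocess import SpectraSet

__all__ = [
    "SpectraTableDialect",
    "ReadRecord",
    "GeneModel",
    "GenotypeMatrix",
    "read_spectra_table",
    "write_spectra_table",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_vcf",
    "read_gene_models",
    "read_fastq",
    "phred_score",
    "filter_reads",
    "write_gwas_results",
    "read_gwas_results",
]


# ---------------------------------------------------------------------------
# spectra tables
# ---------------------------------------------------------------------------

@dataclass
class SpectraTableDialect:
    """How a wide-format spectra CSV is laid out.

    ``orientation`` is ``"samples-as-rows"`` (default: one row per
    sample/replicate, wavelength header) or ``"samples-as-columns"``.
    ``replicate_column`` names an optional integer replicate column.
    """

    orientation: str = "samples-as-rows"
    replicate_column: str | None = None


def read_spectra_table(
    path: str | Path,
    dialect: SpectraTableDialect | None = None,
    role: str = "raw",
) -> SpectraSet:
    """Read a wide-format spectra CSV into a :class:`SpectraSet`.

    The wavelength header must be strictly increasing; every sample shares
    the one grid by construction of the wide format.  Missing cells and
    duplicate (sample, replicate) keys are format errors.
    """
    dialect = dialect or SpectraTableDialect()
    df = pd.read_csv(path)
    if dialect.orientation == "samples-as-columns":
        df = df.set_index(df.columns[0]).T.reset_index(names="sample_id")
    id_cols = [df.columns[0]]
    if dialect.replicate_column is not None:
        if dialect.replicate_column not in df.columns:
            raise ValueError(f"replicate column {dialect.replicate_column!r} absent")
        id_cols.append(dialect.replicate_column)
    try:
        wl = np.asarray([float(c) for c in df.columns if c not in id_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header in {path}: {exc}") from None
    if not np.all(np.diff(wl) > 0):
        raise ValueError(f"wavelength header not strictly increasing in {path}")
    body = df.drop(columns=id_cols).astype(float)
    if body.isna().any().any():
        raise ValueError(f"missing reflectance cells in {path}")
    if dialect.replicate_column is not None:
        index = pd.MultiIndex.from_arrays(
            [df[id_cols[0]], df[dialect.replicate_column].astype(int)],
            names=["sample_id", "replicate"],
        )
    else:
        index = pd.Index(df[id_cols[0]], name="sample_id")
    if index.has_duplicates:
        raise ValueError(f"duplicate sample/replicate keys in {path}")
    body.index = index
    body.columns = wl
    return SpectraSet(body, role=role)


def write_spectra_table(spectra: SpectraSet, path: str | Path) -> None:
    """Write a :class:`SpectraSet` as a wide CSV (wavelength header, 12 sig figs)."""
    df = spectra.data.copy()
    df.columns = [f"{c:g}" for c in spectra.wavelengths]
    df.reset_index().to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read a phenotype CSV (sample_id + one numeric column per trait)."""
    df = pd.read_csv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.columns[out.isna().all()]
    if len(bad):
        raise ValueError(f"non-numeric trait columns in {path}: {list(bad)}")
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    return out


def write_phenotype_table(traits: pd.DataFrame, path: str | Path) -> None:
    traits.to_csv(path, index=True, float_format="%.12g")


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Alt-allele dosage matrix, samples x markers, with NaN for missing."""

    dosages: np.ndarray  # float (n, m); values in {0,1,2} or NaN
    samples: list[str]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with per-marker mean imputation of missing calls."""
        x = self.dosages.copy()
        means = np.nanmean(np.where(np.isnan(x), np.nan, x), axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        idx = np.where(np.isnan(x))
        x[idx] = means[idx[1]]
        return x

    def take_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, keep], list(self.samples))


def _variant_type(ref: str, alt: str) -> str:
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "indel"


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read a VCF 4.x into a variant table and a dosage matrix.

    Genotypes map to alt-allele dosage 0/1/2 with missing preserved as NaN.
    Multiallelic records keep the first ALT with a warning.  SNP/indel type
    follows REF/ALT lengths.  Positions stay 1-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample genotypes (missing GT?)")
    rows = []
    dosage_cols = []
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) == 0:
            raise ValueError(f"{path}: record without ALT at line for pos {rec.POS}")
        if len(rec.ALT) > 1:
            warnings.warn(
                f"multiallelic record at {rec.CHROM}:{rec.POS}; keeping first ALT",
                stacklevel=2,
            )
        alt = rec.ALT[0]
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
                "vtype": _variant_type(rec.REF, alt),
            }
        )
        # gts012: 0/1/2 dosage, 3 = missing
        g = rec.gt_types.astype(float)
        g[g == 3] = np.nan
        dosage_cols.append(g)
    vcf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "vtype"])
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    )
    return variants, GenotypeMatrix(dosages, samples)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A gene span (1-based inclusive) with a free-text functional label."""

    gene_id: str
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("gene model needs a chromosome name")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` features) or 6-column BED.

    BED input is half-open 0-based per convention and is converted to
    1-based inclusive spans.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed6"}:
        genes = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{path}:{ln}: BED line with <4 columns")
                chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
                label = parts[6] if len(parts) > 6 else ""
                genes.append(GeneModel(name, chrom, start + 1, end, label))
        return genes
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{ln}: GFF3 line with <9 columns")
            if parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{ln}: gene feature without ID attribute")
            genes.append(
                GeneModel(
                    gene_id,
                    parts[0],
                    int(parts[3]),
                    int(parts[4]),
                    attrs.get("Note", attrs.get("description", "")),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# sequencing reads
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    """One sequencing read: id, bases over {A,C,G,T,N}, per-base Phred scores."""

    id: str
    bases: str
    quals: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(f"read {self.id}: bases/quals length mismatch")
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id}: negative quality score")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Load FASTQ records (plain or gzip is handled upstream by the caller)."""
    return [
        ReadRecord(rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def phred_score(e: float) -> float:
    """Phred quality for a sequencing error rate: ``Q = -10 * log10(e)``."""
    if not 0 < e <= 1:
        raise ValueError(f"error rate must be in (0, 1], got {e}")
    return -10.0 * math.log10(e)


def filter_reads(
    reads: list[ReadRecord],
    max_n_frac: float = 0.10,
    low_q: int = 10,
    max_lowq_frac: float = 0.50,
) -> tuple[list[ReadRecord], list[tuple[ReadRecord, str]]]:
    """Apply the stated read-quality filters.

    A read is discarded iff its fraction of N bases exceeds ``max_n_frac``
    (strictly: "over 10%") or the fraction of bases with quality below
    ``low_q`` exceeds ``max_lowq_frac`` (strictly: "over 50%").  Boundary
    reads are kept.  Returns ``(kept, discarded)`` with a reason per
    discarded read; order within each partition is preserved.
    """
    kept: list[ReadRecord] = []
    discarded: list[tuple[ReadRecord, str]] = []
    for read in reads:
        n = len(read.bases)
        if n == 0:
            kept.append(read)
            continue
        n_frac = read.bases.count("N") / n
        lowq_frac = sum(q < low_q for q in read.quals) / n
        if n_frac > max_n_frac:
            discarded.append((read, f"N fraction {n_frac:.3f} > {max_n_frac}"))
        elif lowq_frac > max_lowq_frac:
            discarded.append(
                (read, f"low-quality fraction {lowq_frac:.3f} > {max_lowq_frac}")
            )
        else:
            kept.append(read)
    return kept, discarded


# ---------------------------------------------------------------------------
# GWAS result tables
# ---------------------------------------------------------------------------

_GWAS_COLUMNS = ["chrom", "pos", "effect", "se", "stat", "p", "neglog10p"]


def write_gwas_results(result, outdir: str | Path) -> dict[str, Path]:
    """Write a GWAS scan as TSVs: per-marker table, thresholds, intervals.

    Rows sort by (chrom, pos).  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = result.table[_GWAS_COLUMNS].sort_values(["chrom", "pos"]).reset_index(drop=True)
    marker_path = outdir / "markers.tsv"
    table.to_csv(marker_path, sep="\t", index=False, float_format="%.12g")

    thr_path = outdir / "thresholds.tsv"
    pd.DataFrame(
        {
            "name": ["significant", "suggestive"],
            "alpha": [0.01, 0.1],
            "n": [result.threshold_n, result.threshold_n],
            "p_threshold": [result.significant_threshold, result.suggestive_threshold],
        }
    ).to_csv(thr_path, sep="\t", index=False, float_format="%.12g")

    loci_path = outdir / "loci.tsv"
    loci = result.loci if result.loci is not None else pd.DataFrame(
        columns=["chrom", "start", "end", "lead_pos", "lead_p"]
    )
    loci.to_csv(loci_path, sep="\t", index=False, float_format="%.12g")
    return {"markers": marker_path, "thresholds": thr_path, "loci": loci_path}


def read_gwas_results(marker_path: str | Path) -> pd.DataFrame:
    """Read back a per-marker TSV written by :func:`write_gwas_results`."""
    df = pd.read_csv(marker_path, sep="\t")
    missing = [c for c in _GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{marker_path}: missing columns {missing}")
    return df
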