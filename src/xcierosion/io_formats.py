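"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; conversion from the
1-based conventions of VCF and GFF3 happens only at the I/O boundary. All
writers emit UTF-8, tab-delimited, LF-ended text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

XCI_STATUSES = ("inactive", "variable", "escape", "undefined")

ALLELIC_COUNT_COLUMNS = ["sample", "gene_id", "snp_id", "hapA_count", "hapB_count"]


class FormatError(ValueError):
    """A file violated the documented dialect contract."""


class VcfParseError(FormatError):
    """The VCF could not be parsed; carries the underlying htslib message."""


@dataclass(frozen=True)
class PhasedSnp:
    """A heterozygous SNP with its haplotype assignment.

    ``pos`` is 1-based (as printed in the VCF). ``hapA_allele`` and
    ``hapB_allele`` are the bases carried by the two haplotypes; for an
    unphased heterozygote they default to (ref, alt) and ``phase_known``
    is False so downstream code can request a concordance-based phase.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    hapA_allele: str
    hapB_allele: str
    gene_id: str = ""
    phase_known: bool = True
    snp_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP position must be >= 1, got {self.pos}")
        alleles = {self.ref_allele, self.alt_allele}
        if self.hapA_allele == self.hapB_allele:
            raise ValueError("haplotype alleles must differ (heterozygous site)")
        if not {self.hapA_allele, self.hapB_allele} <= alleles:
            raise ValueError("haplotype alleles must be the REF/ALT alleles")


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (0-based half-open) with its erosion-relevant labels."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    band: str = ""
    length_bp: int = 0
    xci_status: str = "undefined"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"{self.gene_id}: need start < end, got [{self.start}, {self.end})"
            )
        if self.xci_status not in XCI_STATUSES:
            raise ValueError(f"unknown XCI status {self.xci_status!r}")
        if self.length_bp == 0:
            object.__setattr__(self, "length_bp", self.end - self.start)


class SignalTrack:
    """Sorted, non-overlapping (chrom, start, end, value) intervals.

    Backed by per-chromosome numpy arrays so metagene binning is a pair of
    ``searchsorted`` calls per query window.
    """

    def __init__(self, intervals: pd.DataFrame):
        required = {"chrom", "start", "end", "value"}
        if not required <= set(intervals.columns):
            raise FormatError(f"signal track needs columns {sorted(required)}")
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in intervals.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            values = sub["value"].to_numpy(dtype=float)
            if np.any(ends <= starts):
                raise FormatError(f"{chrom}: empty or inverted interval")
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"{chrom}: overlapping intervals")
            if not np.all(np.isfinite(values)):
                raise FormatError(f"{chrom}: non-finite signal value")
            self._by_chrom[str(chrom)] = (starts, ends, values)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            pd.DataFrame(
                {"chrom": chrom, "start": s, "end": e, "value": v}
            )
            for chrom, (s, e, v) in sorted(self._by_chrom.items())
        ]
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end", "value"])
        return pd.concat(rows, ignore_index=True)

    def window_mean(self, chrom: str, start: int, end: int) -> float:
        """Coverage-weighted mean over [start, end); uncovered bp count as 0."""
        if end <= start:
            raise ValueError("empty window")
        if chrom not in self._by_chrom:
            raise KeyError(chrom)
        starts, ends, values = self._by_chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float((ov * values[lo:hi]).sum() / (end - start))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str | Path, region_filter: str | None = None) -> list[PhasedSnp]:
    """Read heterozygous SNPs with their phase from a VCF with GT fields.

    Phased heterozygotes ("0|1"/"1|0") are mapped onto haplotype alleles
    (first GT allele -> hapA). Unphased heterozygotes are returned with
    ``phase_known=False``. Homozygous records are dropped; multi-allelic
    sites are skipped with a warning counter (the allelic framework is
    biallelic).
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises bare Exceptions
        raise VcfParseError(f"{path}: {exc}") from exc

    snps: list[PhasedSnp] = []
    n_multiallelic = 0
    try:
        for var in vcf:
            if region_filter is not None and var.CHROM != region_filter:
                continue
            if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
                n_multiallelic += 1
                continue
            gt = var.genotypes[0]  # [alleleA, alleleB, phased]
            a, b, phased = gt[0], gt[1], bool(gt[2])
            if a < 0 or b < 0 or a == b:  # missing or homozygous
                continue
            alleles = (var.REF, var.ALT[0])
            hap_a, hap_b = (alleles[a], alleles[b]) if phased else alleles
            snps.append(
                PhasedSnp(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref_allele=var.REF,
                    alt_allele=var.ALT[0],
                    hapA_allele=hap_a,
                    hapB_allele=hap_b,
                    phase_known=phased,
                    snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                )
            )
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed record: {exc}") from exc
    if n_multiallelic:
        log.warning("%s: skipped %d multi-allelic site(s)", path, n_multiallelic)
    return snps


# ---------------------------------------------------------------------------
# Gene annotation (GFF3 / BED)
# ---------------------------------------------------------------------------

_GFF3_COLUMNS = [
    "chrom", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def _gff3_attr(attributes: str, key: str) -> str:
    for part in attributes.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return ""


def read_gene_annotation(path: str | Path, dialect: str) -> list[GeneAnnotation]:
    """Read gene intervals from GFF3 (``type == gene``) or BED4+.

    GFF3's 1-based closed coordinates are converted to 0-based half-open;
    BED is passed through. Records with a non-positive interval after
    conversion are rejected with a warning.
    """
    path = Path(path)
    if dialect not in ("gff3", "bed"):
        raise FormatError(f"unknown annotation dialect {dialect!r}")
    genes: list[GeneAnnotation] = []
    if dialect == "gff3":
        try:
            df = pd.read_csv(
                path, sep="\t", comment="#", header=None, names=_GFF3_COLUMNS,
                dtype=str,
            )
        except pd.errors.EmptyDataError:
            return []
        df = df[df["type"] == "gene"]
        for row in df.itertuples(index=False):
            start = int(row.start) - 1  # 1-based closed -> 0-based half-open
            end = int(row.end)
            gene_id = _gff3_attr(row.attributes, "ID") or _gff3_attr(row.attributes, "gene_id")
            if end <= start:
                log.warning("%s: rejecting %s, empty interval after conversion", path, gene_id)
                continue
            status = _gff3_attr(row.attributes, "xci_status") or "undefined"
            length = _gff3_attr(row.attributes, "length_bp")
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    chrom=row.chrom,
                    start=start,
                    end=end,
                    strand=row.strand if row.strand in "+-" else "+",
                    band=_gff3_attr(row.attributes, "band"),
                    length_bp=int(length) if length else 0,
                    xci_status=status,
                )
            )
    else:
        try:
            df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
        except pd.errors.EmptyDataError:
            return []
        if df.shape[1] < 4:
            raise FormatError(f"{path}: BED4+ requires at least 4 columns")
        for row in df.itertuples(index=False):
            start, end = int(row[1]), int(row[2])
            if end <= start:
                log.warning("%s: rejecting %s, empty interval", path, row[3])
                continue
            strand = str(row[5]) if df.shape[1] > 5 and str(row[5]) in "+-" else "+"
            genes.append(
                GeneAnnotation(
                    gene_id=str(row[3]), chrom=str(row[0]),
                    start=start, end=end, strand=strand,
                )
            )
    return genes


def write_gene_bed(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def assign_snps_to_genes(
    snps: Sequence[PhasedSnp], genes: Sequence[GeneAnnotation]
) -> list[PhasedSnp]:
    """Attach ``gene_id`` to each SNP contained in a gene interval.

    SNPs outside every interval keep an empty gene_id. First containing
    gene wins when intervals overlap (annotation order).
    """
    from dataclasses import replace

    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for snp in snps:
        zero_based = snp.pos - 1
        gene_id = snp.gene_id
        for g in by_chrom.get(snp.chrom, []):
            if g.start <= zero_based < g.end:
                gene_id = g.gene_id
                break
        out.append(replace(snp, gene_id=gene_id))
    return out


# ---------------------------------------------------------------------------
# Allelic-count and total-count tables
# ---------------------------------------------------------------------------

def read_allelic_counts(path: str | Path) -> pd.DataFrame:
    """Read the per-SNP allelic count TSV.

    Schema: ``sample gene_id snp_id hapA_count hapB_count``. At the SNP level
    the two count columns are oriented on the VCF (REF, ALT) alleles; the
    mapping onto haplotypes is done during aggregation once phase is known.
    Counts must be non-negative integers; missing cells and duplicated
    (sample, gene, snp) keys are errors, never silently filled.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene_id": str, "snp_id": str})
    if list(df.columns) != ALLELIC_COUNT_COLUMNS:
        raise FormatError(
            f"{path}: header must be {ALLELIC_COUNT_COLUMNS}, got {list(df.columns)}"
        )
    if df.empty:
        return df.astype({"hapA_count": np.int64, "hapB_count": np.int64})
    for col in ("hapA_count", "hapB_count"):
        vals = df[col]
        if vals.isna().any():
            bad = int(vals.isna().idxmax())
            raise FormatError(f"{path}: missing {col} at row {bad}")
        as_float = vals.astype(float)
        if not np.all(as_float == np.floor(as_float)) or (as_float < 0).any():
            bad = int(np.flatnonzero((as_float != np.floor(as_float)) | (as_float < 0))[0])
            raise FormatError(f"{path}: {col} not a non-negative integer at row {bad}")
        df[col] = as_float.astype(np.int64)
    key = ["sample", "gene_id", "snp_id"]
    if df.duplicated(key).any():
        dup = df[df.duplicated(key)].iloc[0]
        raise FormatError(
            f"{path}: duplicated key ({dup['sample']}, {dup['gene_id']}, {dup['snp_id']})"
        )
    return df


def write_allelic_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_counts_matrix(path: str | Path) -> pd.DataFrame:
    """Read a gene_id x sample integer count matrix (genes as the index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy()
    if mat.size and (not np.issubdtype(mat.dtype, np.number) or (mat < 0).any()):
        raise FormatError(f"{path}: counts must be non-negative numbers")
    return df


def write_counts_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="gene_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# bedGraph signal
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | Path) -> SignalTrack:
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    return SignalTrack(df)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def read_methylation_table(path: str | Path) -> pd.DataFrame:
    """Read a promoter-methylation probe table: ``chrom pos beta`` (0-based pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64, "beta": float})
    if not {"chrom", "pos", "beta"} <= set(df.columns):
        raise FormatError(f"{path}: methylation table needs chrom/pos/beta columns")
    if ((df["beta"] < 0) | (df["beta"] > 1)).any():
        raise FormatError(f"{path}: beta outside [0, 1]")
    return df


def read_xci_reference(path: str | Path) -> pd.DataFrame:
    """Read the XCI-status reference: TSV ``gene_id status``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "status"} <= set(df.columns):
        raise FormatError(f"{path}: reference needs gene_id/status columns")
    bad = set(df["status"]) - set(XCI_STATUSES)
    if bad:
        raise FormatError(f"{path}: unknown status values {sorted(bad)}")
    return df
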