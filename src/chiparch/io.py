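"""Readers and writers for the plain-text formats the pipeline consumes.

Peaks: BED6, narrowPeak, and a 1-based tabular peak-table layout
(chromosome, region start, region end, genomic position, TSS distance,
gene name, gene id, raw tags, normalized tags).  Reads: a minimal
tab-separated alignment table (chrom, pos5, strand, length) plus a SAM
adapter.  Genomes: FASTA via pyfaidx.  Gene models and result tables:
tab-separated files.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import pandas as pd
import pyfaidx
import pysam

from .intervals import GeneModel, GenomicInterval, Peak, UnionPeak, venn_counts
from .peaks import LibraryStats, ReadAlignment

__all__ = [
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_peak_table",
    "read_alignment_table",
    "write_alignment_table",
    "read_alignments_sam",
    "read_gene_models",
    "write_gene_models",
    "open_genome",
    "fetch_sequence",
    "write_fasta",
    "write_union_peaks",
    "write_venn_table",
    "read_library_stats",
    "write_library_stats",
]


# --- peaks -----------------------------------------------------------------

def read_bed(path, source: str = "") -> list:
    """Read peaks from BED (>=3 columns; name taken from column 4)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            name = f[3] if len(f) > 3 and f[3] != "." else ""
            peaks.append(Peak(iv, name=name, source=source))
    return peaks


def write_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name or '.'}\t0\t.\n")


def read_narrowpeak(path, source: str = "") -> list:
    """Read ENCODE narrowPeak.  Columns 7-10 are optional; column 10
    (summit offset from start) is honored when >= 0.  The score column
    carries the raw tag count and signalValue the normalized count, the
    convention :func:`write_narrowpeak` uses."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            name = f[3] if len(f) > 3 and f[3] != "." else ""
            raw = int(float(f[4])) if len(f) > 4 and f[4] != "." else 0
            signal = float(f[6]) if len(f) > 6 else -1.0
            summit = None
            if len(f) > 9:
                off = int(f[9])
                if off >= 0:
                    summit = iv.start + off
            peaks.append(
                Peak(
                    iv,
                    name=name,
                    raw_count=raw,
                    norm_count=signal if signal >= 0 else None,
                    summit=summit,
                    source=source,
                )
            )
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            signal = p.norm_count if p.norm_count is not None else -1.0
            offset = p.summit - iv.start if p.summit is not None else -1
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name or '.'}\t{p.raw_count}"
                f"\t.\t{signal:.4f}\t-1\t-1\t{offset}\n"
            )


_PEAK_TABLE_COLS = [
    "chromosome", "start", "end", "genomic_position", "tss_distance",
    "gene_name", "gene_id", "raw_tags", "normalized_tags",
]


def read_peak_table(path, source: str = "") -> list:
    """Read a 1-based tabular peak table.

    Expected columns: chromosome, region start (1-based, converted to
    0-based), region end, genomic position class, TSS distance, gene name,
    gene id, raw tag count, normalized tag count.  A header row is
    detected and skipped.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    try:
        int(df.iloc[0, 1])
    except (ValueError, TypeError):
        df = df.iloc[1:]
    df.columns = _PEAK_TABLE_COLS[: df.shape[1]]
    peaks = []
    for _, row in df.iterrows():
        iv = GenomicInterval(str(row["chromosome"]), int(row["start"]) - 1, int(row["end"]))
        raw = int(float(row["raw_tags"])) if "raw_tags" in row else 0
        norm = float(row["normalized_tags"]) if "normalized_tags" in row else None
        name = str(row["gene_name"]) if "gene_name" in row else ""
        peaks.append(Peak(iv, name=name, raw_count=raw, norm_count=norm, source=source))
    return peaks


# --- reads -----------------------------------------------------------------

def read_alignment_table(path) -> list:
    """Read the minimal alignment table: chrom, pos5, strand, length."""
    reads = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, pos5, strand, length = line.split("\t")[:4]
            reads.append(ReadAlignment(chrom, int(pos5), strand, int(length)))
    return reads


def write_alignment_table(reads: Sequence[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos5\tstrand\tlength\n")
        for r in reads:
            fh.write(f"{r.chrom}\t{r.pos5}\t{r.strand}\t{r.length}\n")


def read_alignments_sam(path) -> list:
    """Adapter for standard alignment format (SAM/BAM/CRAM) via pysam.

    The 5' position is ``reference_start`` for forward reads and
    ``reference_end - 1`` for reverse reads; unmapped and secondary
    records are skipped.
    """
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            length = rec.query_length or rec.infer_read_length() or 0
            if length <= 0:
                continue
            if rec.is_reverse:
                reads.append(ReadAlignment(rec.reference_name, rec.reference_end - 1, "-", length))
            else:
                reads.append(ReadAlignment(rec.reference_name, rec.reference_start, "+", length))
    return reads


# --- gene models -----------------------------------------------------------

def read_gene_models(path) -> list:
    """Read gene models: gene_id, chrom, strand, tss, exons ('s-e,s-e')."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene_id, chrom, strand, tss, exons_str = line.split("\t")[:5]
            exons = []
            if exons_str and exons_str != ".":
                for part in exons_str.split(","):
                    s, e = part.split("-")
                    exons.append(GenomicInterval(chrom, int(s), int(e)))
            genes.append(GeneModel(gene_id, chrom, strand, int(tss), tuple(exons)))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tchrom\tstrand\ttss\texons\n")
        for g in genes:
            exons = ",".join(f"{ex.start}-{ex.end}" for ex in g.exons) or "."
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{exons}\n")


# --- genome ----------------------------------------------------------------

def open_genome(path):
    """Open an indexed FASTA for random access (pyfaidx)."""
    return pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)


def fetch_sequence(genome, chrom: str, start: int, end: int) -> tuple:
    """Fetch ``[start, end)`` from a genome mapping or indexed FASTA.

    Clips to chromosome bounds and returns ``(sequence, start, end)`` with
    the actual bounds used.  Raises ``KeyError`` for a missing chromosome.
    """
    if isinstance(genome, Mapping):
        seq = genome[chrom]
    else:
        if chrom not in genome.keys():
            raise KeyError(chrom)
        seq = genome[chrom]
    n = len(seq)
    lo, hi = max(0, start), min(end, n)
    if lo >= hi:
        return "", lo, lo
    return str(seq[lo:hi]), lo, hi


def write_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --- result tables ---------------------------------------------------------

def write_union_peaks(union_peaks: Sequence[UnionPeak], path) -> None:
    """Write union peaks as BED3 plus a membership column."""
    with open(path, "w") as fh:
        for up in union_peaks:
            iv = up.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{up.signature}\n")


def write_venn_table(union_peaks: Sequence[UnionPeak], path) -> None:
    """Write Venn cell counts as a two-column table (signature, count)."""
    counts = venn_counts(union_peaks)
    with open(path, "w") as fh:
        fh.write("signature\tcount\n")
        for sig in sorted(counts):
            fh.write(f"{sig}\t{counts[sig]}\n")


def read_library_stats(path) -> dict:
    stats = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            label, total = line.split("\t")[:2]
            stats[label] = LibraryStats(label, int(total))
    return stats


def write_library_stats(stats: Sequence[LibraryStats], path) -> None:
    with open(path, "w") as fh:
        fh.write("#label\ttotal_unique_reads\n")
        for s in stats:
            fh.write(f"{s.label}\t{s.total_unique_reads}\n")
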