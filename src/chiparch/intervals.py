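"""Interval algebra for ChIP-seq peak-set integration.

All coordinates are 0-based, half-open ``[start, end)``.  Two intervals
overlap iff they share at least one base under these semantics
(``a.start < b.end and b.start < a.end``); book-ended intervals do not
overlap.  These conventions match BED and are applied uniformly to peak
merging (Venn construction), consensus/exclusion filtering and
TSS annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Peak",
    "UnionPeak",
    "GeneModel",
    "merge_overlap_union",
    "overlap_filter",
    "nearest_tss",
    "classify_location",
    "venn_counts",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a nonempty string")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak: an interval plus tag-count annotation.

    ``raw_count`` is the number of (extended) reads overlapping the peak in
    the treatment library; ``norm_count`` the depth-normalized equivalent
    (``None`` until normalization has been applied); ``control_raw_count``
    the raw count in the matched control (IgG or knockout-cell) library.
    ``summit`` is the base of maximal extended-read coverage, when called.
    """

    interval: GenomicInterval
    name: str = ""
    raw_count: int = 0
    norm_count: Optional[float] = None
    control_raw_count: int = 0
    summit: Optional[int] = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.raw_count < 0 or self.control_raw_count < 0:
            raise ValueError("tag counts must be non-negative")
        if self.norm_count is not None and self.norm_count < 0:
            raise ValueError("norm_count must be non-negative")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )

    @property
    def anchor(self) -> int:
        """Summit if set, else the interval midpoint; used for distances."""
        return self.summit if self.summit is not None else self.interval.midpoint

    @property
    def id(self) -> str:
        if self.name:
            return self.name
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


@dataclass(frozen=True)
class UnionPeak:
    """A merged interval labelled with the peak sets overlapping it."""

    interval: GenomicInterval
    membership: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.membership:
            raise ValueError("membership must be nonempty")

    @property
    def signature(self) -> str:
        return "&".join(sorted(self.membership))


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: TSS plus exon structure on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValueError("all exons must be on the gene's chromosome")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = ex.end
        lo, hi = self.span
        if not (lo <= self.tss < hi):
            raise ValueError("tss must lie within the gene span")

    @property
    def span(self) -> tuple:
        """Genomic span covered by the gene (includes the TSS base)."""
        starts = [self.tss] + [ex.start for ex in self.exons]
        ends = [self.tss + 1] + [ex.end for ex in self.exons]
        return min(starts), max(ends)


def _labeled_sets(peak_sets) -> list:
    if isinstance(peak_sets, Mapping):
        items = list(peak_sets.items())
    else:
        items = [(label, peaks) for label, peaks in peak_sets]
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate peak-set labels: {dupes}")
    return items


def merge_overlap_union(peak_sets) -> list:
    """Build the union of labelled peak sets and assign set membership.

    Overlapping intervals (>=1 shared base) from any input set are merged
    into a single :class:`UnionPeak` whose ``membership`` is the set of
    labels contributing at least one overlapping peak.  Venn cell counts
    are the number of union peaks per membership signature (see
    :func:`venn_counts`).

    Parameters
    ----------
    peak_sets
        Mapping of label -> sequence of :class:`Peak`, or an iterable of
        ``(label, peaks)`` pairs.  Labels must be unique.
    """
    items = _labeled_sets(peak_sets)
    by_chrom: dict = {}
    for label, peaks in items:
        for p in peaks:
            iv = p.interval
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, label))

    out = []
    for chrom in sorted(by_chrom):
        rows = sorted(by_chrom[chrom])
        cur_start, cur_end, members = rows[0][0], rows[0][1], {rows[0][2]}
        for start, end, label in rows[1:]:
            if start < cur_end:  # >=1 bp overlap with the running union
                cur_end = max(cur_end, end)
                members.add(label)
            else:
                out.append(
                    UnionPeak(GenomicInterval(chrom, cur_start, cur_end), frozenset(members))
                )
                cur_start, cur_end, members = start, end, {label}
        out.append(
            UnionPeak(GenomicInterval(chrom, cur_start, cur_end), frozenset(members))
        )
    return out


def venn_counts(union_peaks: Sequence[UnionPeak]) -> dict:
    """Venn cell counts: membership signature -> number of union peaks."""
    counts: dict = {}
    for up in union_peaks:
        counts[up.signature] = counts.get(up.signature, 0) + 1
    return counts


def _reference_trees(reference: Iterable[Peak]) -> dict:
    trees: dict = {}
    for p in reference:
        iv = p.interval
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def overlap_filter(query: Sequence[Peak], reference: Sequence[Peak], mode: str = "keep") -> list:
    """Keep or drop query peaks by >=1 bp overlap with any reference peak.

    ``mode='keep'`` retains overlapping query peaks (two-antibody consensus);
    ``mode='drop'`` retains the complement (knockout-control exclusion).
    Query peaks are returned unmodified, so keep and drop partition the query.
    """
    if mode not in ("keep", "drop"):
        raise ValueError(f"mode must be 'keep' or 'drop', got {mode!r}")
    trees = _reference_trees(reference)
    out = []
    for p in query:
        iv = p.interval
        hit = iv.chrom in trees and bool(trees[iv.chrom].overlap(iv.start, iv.end))
        if (hit and mode == "keep") or (not hit and mode == "drop"):
            out.append(p)
    return out


def nearest_tss(peak: Peak, gene_models: Sequence[GeneModel]):
    """Nearest TSS to the peak anchor (summit, or midpoint if unset).

    Returns ``(gene_id, signed_distance)`` where the distance is positive
    when the anchor lies downstream of the TSS in the gene's orientation.
    Ties are broken by smaller TSS coordinate, then gene_id.  Returns
    ``(None, None)`` when no gene lies on the peak's chromosome.
    """
    if not gene_models:
        raise ValueError("at least one gene model is required")
    anchor = peak.anchor
    chrom = peak.interval.chrom
    candidates = [g for g in gene_models if g.chrom == chrom]
    if not candidates:
        log.debug("no gene model on %s; peak %s unannotated", chrom, peak.id)
        return None, None
    best = min(candidates, key=lambda g: (abs(anchor - g.tss), g.tss, g.gene_id))
    distance = anchor - best.tss if best.strand == "+" else best.tss - anchor
    return best.gene_id, distance


def classify_location(peak: Peak, gene_models: Sequence[GeneModel], tss_window: int = 500) -> str:
    """Classify a peak as ``TSS``, ``intragenic`` or ``intergenic``.

    ``TSS`` when the anchor lies within ``tss_window`` bp of the nearest
    TSS; otherwise ``intragenic`` when it falls inside any gene span;
    otherwise ``intergenic``.
    """
    if tss_window <= 0:
        raise ValueError("tss_window must be positive")
    _, distance = nearest_tss(peak, gene_models)
    if distance is not None and abs(distance) <= tss_window:
        return "TSS"
    anchor = peak.anchor
    chrom = peak.interval.chrom
    for g in gene_models:
        if g.chrom != chrom:
            continue
        lo, hi = g.span
        if lo <= anchor < hi:
            return "intragenic"
    return "intergenic"
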