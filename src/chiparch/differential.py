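"""Differential occupancy between conditions at fixed peak positions.

Compares depth-normalized tag counts of one factor between two conditions
(e.g. wild-type vs knockout of a co-binding factor) at a reference peak
set, computes pseudocounted wt/ko ratios, and stratifies the ratios by
co-binding status.  No count-model significance testing is performed:
occupancy change is reported as a continuous ratio plus a configurable
fold-change label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import Peak, overlap_filter
from .peaks import LibraryStats, ReadAlignment, annotate_counts, normalize_count

__all__ = [
    "OccupancyComparison",
    "count_reads_in_peak",
    "occupancy_ratio",
    "cobound_flags",
    "compare_occupancy",
    "stratify_by_cobinding",
]


@dataclass(frozen=True)
class OccupancyComparison:
    peak_id: str
    norm_a: float
    norm_b: float
    ratio: float
    cobound: bool


def count_reads_in_peak(peak: Peak, reads: Sequence[ReadAlignment], extension: int = 200) -> int:
    """Number of reads whose extended span overlaps the peak by >= 1 bp."""
    iv = peak.interval
    n = 0
    for r in reads:
        if r.chrom != iv.chrom:
            continue
        s, e = r.extended_span(extension)
        if s < iv.end and e > iv.start:
            n += 1
    return n


def occupancy_ratio(norm_a: float, norm_b: float, pseudocount: float = 0.5) -> float:
    """Pseudocounted ratio ``(norm_a + pc) / (norm_b + pc)``."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if norm_a < 0 or norm_b < 0:
        raise ValueError("normalized counts must be non-negative")
    return (norm_a + pseudocount) / (norm_b + pseudocount)


def cobound_flags(peaks: Sequence[Peak], reference: Sequence[Peak]) -> list:
    """Per-peak co-binding flags from an overlap filter against a second
    factor's peak set."""
    kept = {id(p) for p in overlap_filter(peaks, reference, mode="keep")}
    return [id(p) in kept for p in peaks]


def compare_occupancy(
    peaks: Sequence[Peak],
    reads_a: Sequence[ReadAlignment],
    stats_a: LibraryStats,
    reads_b: Sequence[ReadAlignment],
    stats_b: LibraryStats,
    cobound: Sequence[bool],
    extension: int = 200,
    pseudocount: float = 0.5,
    scale: float = 1e6,
) -> list:
    """Per-peak normalized counts in two conditions plus their ratio.

    Counts are evaluated at the given (reference-condition) peak
    coordinates in both libraries, normalized to ``scale`` reads, and the
    a/b ratio computed with a pseudocount.
    """
    if len(cobound) != len(peaks):
        raise ValueError("cobound flags must align with peaks")
    with_a = annotate_counts(peaks, reads_a, extension, target="raw")
    with_b = annotate_counts(peaks, reads_b, extension, target="raw")
    out = []
    for p, pa, pb, flag in zip(peaks, with_a, with_b, cobound):
        na = normalize_count(pa.raw_count, stats_a.total_unique_reads, scale)
        nb = normalize_count(pb.raw_count, stats_b.total_unique_reads, scale)
        out.append(
            OccupancyComparison(p.id, na, nb, occupancy_ratio(na, nb, pseudocount), bool(flag))
        )
    return out


def _group_summary(ratios: np.ndarray, fold_threshold: float) -> dict:
    if ratios.size == 0:
        return {"n": 0, "median_ratio": None,
                "frac_attenuated": None, "frac_potentiated": None}
    return {
        "n": int(ratios.size),
        "median_ratio": float(np.median(ratios)),
        "frac_attenuated": float(np.mean(ratios >= fold_threshold)),
        "frac_potentiated": float(np.mean(ratios <= 1 / fold_threshold)),
    }


def stratify_by_cobinding(
    comparisons: Sequence[OccupancyComparison],
    fold_threshold: float = 2.0,
) -> tuple:
    """Group-wise ratio summaries plus per-peak change labels.

    Returns ``(per_peak, summaries)``: a DataFrame with one row per peak
    (id, norm counts, ratio, cobound, label in attenuated/unchanged/
    potentiated) and a dict of summaries for the ``cobound`` and
    ``not_cobound`` groups (n, median ratio, fraction attenuated with
    ratio >= threshold, fraction potentiated with ratio <= 1/threshold).
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")

    def label(r: float) -> str:
        if r >= fold_threshold:
            return "attenuated"
        if r <= 1 / fold_threshold:
            return "potentiated"
        return "unchanged"

    per_peak = pd.DataFrame(
        {
            "peak_id": [c.peak_id for c in comparisons],
            "norm_a": [c.norm_a for c in comparisons],
            "norm_b": [c.norm_b for c in comparisons],
            "ratio": [c.ratio for c in comparisons],
            "cobound": [c.cobound for c in comparisons],
            "label": [label(c.ratio) for c in comparisons],
        }
    )
    ratios = per_peak["ratio"].to_numpy()
    mask = per_peak["cobound"].to_numpy(dtype=bool)
    summaries = {
        "cobound": _group_summary(ratios[mask], fold_threshold),
        "not_cobound": _group_summary(ratios[~mask], fold_threshold),
    }
    return per_peak, summaries
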