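"""Consensus-motif scanning and summit-centered motif architecture.

Scans summit-centered sequence windows for canonical promoter elements
(the CCAAT box bound by Nf-y; the GC box bound by Sp1/Sp3 zinc fingers)
on both strands, summarizes motif content (fraction of windows with >= k
perfect matches), enumerates tandem pairs at a constrained start-to-start
spacing (30-50 nt by default), and builds summit-relative positional
profiles with bimodal mode separation.

Positional enrichment here is a positional-density profile (binned hit
midpoints with optional Gaussian smoothing); it characterizes central
enrichment shape without computing a central-enrichment p-value.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .intervals import Peak

__all__ = [
    "Motif",
    "MotifHit",
    "Window",
    "PositionalProfile",
    "CCAAT_BOX",
    "GC_BOX",
    "GC_BOX_LONG",
    "extract_windows",
    "scan_consensus",
    "summit_relative",
    "motif_content_summary",
    "tandem_pairs",
    "positional_profile",
    "mode_separation",
]

# IUPAC code -> the set of plain bases it matches.  A sequence 'N' never
# matches (character classes list explicit bases only).
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def _iupac_regex(consensus: str) -> str:
    parts = []
    for c in consensus:
        bases = _IUPAC[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


@dataclass(frozen=True)
class Motif:
    """A named IUPAC consensus motif."""

    name: str
    consensus: str

    def __post_init__(self) -> None:
        cons = self.consensus.upper()
        if not cons:
            raise ValueError("consensus must be nonempty")
        bad = set(cons) - set(_IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in consensus: {sorted(bad)}")
        object.__setattr__(self, "consensus", cons)

    @property
    def length(self) -> int:
        return len(self.consensus)

    @property
    def revcomp(self) -> str:
        return str(Seq(self.consensus).reverse_complement())

    @property
    def is_palindromic(self) -> bool:
        return self.consensus == self.revcomp


CCAAT_BOX = Motif("CCAAT-box", "CCAAT")
GC_BOX = Motif("GC-box", "GGGCGGG")
GC_BOX_LONG = Motif("GC-box-long", "GGGGCGGGG")


@dataclass(frozen=True)
class MotifHit:
    """A strand-aware motif occurrence.

    ``offset`` is the position of the match's lowest genomic coordinate
    (window-local from :func:`scan_consensus`; summit-relative after
    :func:`summit_relative`).
    """

    offset: int
    strand: str
    length: int = 0

    @property
    def midpoint(self) -> float:
        return self.offset + (self.length - 1) / 2


@dataclass(frozen=True)
class Window:
    """A summit-centered sequence window."""

    peak_id: str
    chrom: str
    start: int
    end: int
    summit: int
    seq: str


@dataclass
class PositionalProfile:
    """Binned density of motif-hit midpoints relative to peak summits."""

    halfwidth: int
    binwidth: int
    counts: np.ndarray
    smoothed: np.ndarray
    n_sequences: int

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return -self.halfwidth + self.binwidth * (np.arange(self.n_bins) + 0.5)


def extract_windows(
    peaks: Sequence[Peak],
    genome,
    halfwidth: int = 150,
) -> tuple:
    """Uppercased sequences ``[summit - halfwidth, summit + halfwidth)``.

    ``genome`` may be a ``{chrom: sequence}`` mapping or an indexed FASTA
    (``pyfaidx.Fasta``).  Windows are truncated at chromosome ends.
    Per-peak problems (missing chromosome or summit) are returned as error
    records rather than raised.
    """
    from .io import fetch_sequence  # local import to avoid a cycle

    windows: list = []
    errors: list = []
    for p in peaks:
        if p.summit is None:
            errors.append({"peak_id": p.id, "error": "summit unset"})
            continue
        chrom = p.interval.chrom
        try:
            lo = max(0, p.summit - halfwidth)
            seq, lo, hi = fetch_sequence(genome, chrom, lo, p.summit + halfwidth)
        except KeyError:
            errors.append({"peak_id": p.id, "error": f"chromosome {chrom!r} not in genome"})
            continue
        windows.append(Window(p.id, chrom, lo, hi, p.summit, seq.upper()))
    return windows, errors


def scan_consensus(sequence: str, motif: Motif) -> list:
    """All exact IUPAC matches of a motif on both strands.

    Forward-strand matches are reported with strand ``+``; matches of the
    reverse complement with strand ``-``.  Offsets are the match's lowest
    coordinate in the scanned sequence; overlapping matches are all
    reported.  For palindromic consensi the two strands would yield
    sequence-identical duplicates, so only ``+`` hits are reported.
    """
    seq = sequence.upper()
    hits = []
    fwd = re.compile(f"(?=({_iupac_regex(motif.consensus)}))")
    for m in fwd.finditer(seq):
        hits.append(MotifHit(m.start(), "+", motif.length))
    if not motif.is_palindromic:
        rev = re.compile(f"(?=({_iupac_regex(motif.revcomp)}))")
        for m in rev.finditer(seq):
            hits.append(MotifHit(m.start(), "-", motif.length))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def summit_relative(hits: Sequence[MotifHit], window: Window) -> list:
    """Convert window-local hit offsets to summit-relative offsets."""
    shift = window.start - window.summit
    return [MotifHit(h.offset + shift, h.strand, h.length) for h in hits]


def motif_content_summary(
    windows: Sequence[Window],
    motif: Motif,
    k: int = 2,
) -> tuple:
    """Fraction of windows with >= ``k`` motif hits, plus per-window counts.

    Returns ``(fraction, counts)`` where ``counts`` maps peak id to hit
    count; the fraction is ``None`` for an empty window list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = {w.peak_id: len(scan_consensus(w.seq, motif)) for w in windows}
    if not counts:
        return None, counts
    frac = sum(1 for c in counts.values() if c >= k) / len(counts)
    return frac, counts


def tandem_pairs(hits: Sequence[MotifHit], dmin: int = 30, dmax: int = 50) -> list:
    """All unordered hit pairs at start-to-start distance in [dmin, dmax]."""
    if dmin > dmax:
        raise ValueError("dmin must be <= dmax")
    pairs = []
    for a, b in combinations(hits, 2):
        d = abs(a.offset - b.offset)
        if dmin <= d <= dmax:
            pairs.append((a, b) if a.offset <= b.offset else (b, a))
    return pairs


def positional_profile(
    hit_sets: Iterable[Sequence[MotifHit]],
    halfwidth: int,
    binwidth: int = 5,
    smoothing_sigma: float = 5.0,
) -> PositionalProfile:
    """Histogram of summit-relative hit midpoints across windows.

    Raw counts are preserved; a Gaussian-smoothed copy (sigma in bp) is
    carried alongside for mode detection.  Midpoints are clipped into
    ``[-halfwidth, halfwidth)`` so the raw histogram always sums to the
    total number of hits.
    """
    n_bins = math.ceil(2 * halfwidth / binwidth)
    edges = -halfwidth + binwidth * np.arange(n_bins + 1)
    mids = []
    n_seq = 0
    for hits in hit_sets:
        n_seq += 1
        mids.extend(h.midpoint for h in hits)
    arr = np.asarray(mids, dtype=float)
    if arr.size:
        arr = np.clip(arr, -halfwidth, edges[-1] - 1e-9)
    counts, _ = np.histogram(arr, bins=edges)
    counts = counts.astype(float)
    if smoothing_sigma > 0:
        smoothed = gaussian_filter1d(counts, sigma=smoothing_sigma / binwidth, mode="constant")
    else:
        smoothed = counts.copy()
    return PositionalProfile(halfwidth, binwidth, counts, smoothed, n_seq)


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-bin peak position (in bins, relative to bin i) by parabola fit."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def mode_separation(profile: PositionalProfile, min_prominence_frac: float = 0.1) -> Optional[float]:
    """Distance (bp) between the flanking modes of a bimodal profile.

    Local maxima of the smoothed profile with prominence >= 10% of its
    global maximum are located; if at least one lies on each side of the
    summit, the distance between the most prominent mode on each side is
    returned (mode centers refined by parabolic interpolation).  Returns
    ``None`` for unimodal/central or empty profiles.
    """
    y = profile.smoothed
    if y.size == 0 or y.max() <= 0:
        return None
    idx, props = find_peaks(y, prominence=min_prominence_frac * y.max())
    if len(idx) < 2:
        return None
    centers = profile.bin_centers
    modes = []
    for i, prom in zip(idx, props["prominences"]):
        center = centers[i] + _parabolic_refine(y, i) * profile.binwidth
        modes.append((prom, center))
    neg = [m for m in modes if m[1] < 0]
    pos = [m for m in modes if m[1] > 0]
    if not neg or not pos:
        return None
    best_neg = max(neg)[1]
    best_pos = max(pos)[1]
    return float(best_pos - best_neg)
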