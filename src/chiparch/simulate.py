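"""Seeded synthetic ChIP-seq data with planted ground truth.

Generates a toy genome, gene annotation, peaks of four motif-architecture
classes and two-condition single-end 50 bp reads, so that every pipeline
stage (filtering, summit calling, Venn construction, TSS annotation,
motif architecture, differential occupancy) can be validated against
known truth without any external data.

Peak classes
------------
``tandem_CCAAT``
    two CCAAT/ATTGG motifs planted symmetrically about the summit at a
    start-to-start spacing drawn from Normal(spacing_mean, spacing_sd)
    clipped to ``spacing_clip`` (the promoter architecture of tandem
    Nf-y sites);
``central_GC``
    one GC box (GGGCGGG, random strand) centered at the summit;
``both``
    tandem CCAAT pair plus a central GC box;
``none``
    no planted motif.

Before planting, every spontaneous occurrence of the configured motifs
within the summit window is disrupted by single-base substitution, so the
planted architecture is exactly what a scan of the emitted genome finds.
Tandem-class and ``both``-class peaks are "co-bound" by the second factor:
in the knockout (``ko``) condition their fragment rate is divided by
``cofactor_dependency_fold``, emulating attenuated occupancy at co-bound
sites.  A ``control`` condition (background only, no enrichment) plays the
role of the IgG/input library for signal-to-background filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .intervals import GeneModel, GenomicInterval, Peak
from .motifs import CCAAT_BOX, GC_BOX, Motif, scan_consensus
from .peaks import LibraryStats, ReadAlignment

__all__ = [
    "CLASSES",
    "CONDITIONS",
    "SimConfig",
    "TruthPeak",
    "SimulatedReference",
    "generate_reference",
    "simulate_reads",
    "candidate_peaks",
    "synthesize_windows",
    "truth_frame",
]

CLASSES = ("tandem_CCAAT", "central_GC", "both", "none")
CONDITIONS = ("wt", "ko", "control")
_COND_KEY = {"wt": 10, "ko": 11, "control": 12}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic experiment.

    ``enrichment_fold`` is the peak fragment rate relative to background;
    the expected fragment count at a peak is ``enrichment_fold *
    peak_read_scale``.  In the ko condition the rate at co-bound peaks is
    divided by ``cofactor_dependency_fold``.  ``background_depth`` is in
    reads per kb.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_peaks_per_class: int = 50
    class_counts: Optional[Mapping[str, int]] = None
    spacing_mean: float = 35.0
    spacing_sd: float = 5.0
    spacing_clip: tuple = (30, 50)
    enrichment_fold: float = 10.0
    cofactor_dependency_fold: float = 3.0
    fragment_mean: int = 200
    fragment_sd: float = 20.0
    read_length: int = 50
    background_depth: float = 10.0
    peak_read_scale: float = 10.0
    min_peak_spacing: int = 5000
    tss_fraction: float = 0.9
    gc_content: float = 0.40
    window_halfwidth: int = 150

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.chrom_length, self.read_length,
               self.fragment_mean, self.min_peak_spacing) <= 0:
            raise ValueError("size parameters must be positive")
        lo, hi = self.spacing_clip
        if not (0 < lo <= hi < 2 * self.window_halfwidth):
            raise ValueError("spacing_clip must fit inside the summit window")
        if self.class_counts is not None:
            unknown = set(self.class_counts) - set(CLASSES)
            if unknown:
                raise ValueError(f"unknown peak classes: {sorted(unknown)}")

    def counts(self) -> dict:
        if self.class_counts is not None:
            return {c: int(self.class_counts.get(c, 0)) for c in CLASSES}
        return {c: self.n_peaks_per_class for c in CLASSES}


@dataclass(frozen=True)
class TruthPeak:
    """Ground truth for one planted peak."""

    peak_id: str
    cls: str
    chrom: str
    summit: int
    motifs: tuple  # of (start, strand, motif name)
    spacing: Optional[int]
    cobound: bool
    enrichment_wt: float
    enrichment_ko: float


@dataclass
class SimulatedReference:
    genome: dict
    genes: list
    truth: list
    config: SimConfig


def _rng(config: SimConfig, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(key,)))


def _random_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _encode(text: str) -> np.ndarray:
    lut = np.zeros(128, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(text.encode("ascii"), dtype=np.uint8)]


def _find_all(hay: str, needles: Sequence[str]) -> list:
    """(position, needle) of every occurrence, overlapping included."""
    occ = []
    for needle in needles:
        start = hay.find(needle)
        while start != -1:
            occ.append((start, needle))
            start = hay.find(needle, start + 1)
    return occ


def _disrupt_region(
    codes: np.ndarray,
    lo: int,
    hi: int,
    forbidden: Sequence[str],
    rng: np.random.Generator,
    protected: Sequence[tuple] = (),
) -> None:
    """Mutate single bases until no forbidden string occurs in [lo, hi).

    ``protected`` spans (planted motifs) are never mutated; an occurrence
    is broken at one of its unprotected bases.  Mutation can in principle
    create a new occurrence, so the region is rescanned until clean.
    """
    prot = sorted(protected)

    def is_protected(pos: int) -> bool:
        return any(s <= pos < e for s, e in prot)

    for _ in range(50):
        text = _codes_to_str(codes[lo:hi])
        occ = _find_all(text, forbidden)
        occ = [
            (pos, needle)
            for pos, needle in occ
            if (lo + pos, lo + pos + len(needle)) not in prot
        ]
        if not occ:
            return
        for pos, needle in occ:
            sites = [lo + pos + j for j in range(len(needle)) if not is_protected(lo + pos + j)]
            if not sites:  # fully shadowed by protected spans; cannot occur
                continue
            site = sites[len(sites) // 2]
            current = codes[site]
            codes[site] = rng.choice([b for b in range(4) if b != current])
    raise RuntimeError("motif disruption did not converge")


def _place_summits(config: SimConfig, rng: np.random.Generator) -> list:
    """Deterministic jittered-slot placement keeping summits apart."""
    counts = config.counts()
    total = sum(counts.values())
    margin = config.window_halfwidth + config.fragment_mean + 50
    usable = config.chrom_length - 2 * margin
    capacity = config.n_chroms * (usable // config.min_peak_spacing)
    if total > capacity:
        raise ValueError(
            f"cannot place {total} peaks: genome fits at most {capacity} "
            f"at min_peak_spacing={config.min_peak_spacing}"
        )
    per_chrom = [total // config.n_chroms] * config.n_chroms
    for i in range(total % config.n_chroms):
        per_chrom[i] += 1
    out = []
    for ci, k in enumerate(per_chrom):
        if k == 0:
            continue
        chrom = f"chr{ci + 1}"
        slot = usable // k
        jitter_max = max(slot - config.min_peak_spacing, 1)
        for j in range(k):
            summit = margin + j * slot + int(rng.integers(0, jitter_max))
            out.append((chrom, summit))
    return out


def generate_reference(config: SimConfig) -> SimulatedReference:
    """Generate genome, gene models and planted-peak truth.

    Background sequence is i.i.d. at the configured GC content; summit
    windows are purged of spontaneous CCAAT/GC-box occurrences before
    planting, and the emitted genome is verified against the recorded
    truth (a scan of each window finds exactly the planted hits).
    """
    rng_genome = _rng(config, 0)
    rng_plant = _rng(config, 1)
    rng_genes = _rng(config, 2)

    chrom_codes = {
        f"chr{i + 1}": _random_codes(rng_genome, config.chrom_length, config.gc_content)
        for i in range(config.n_chroms)
    }

    placements = _place_summits(config, rng_plant)
    counts = config.counts()
    classes = [c for c in CLASSES for _ in range(counts[c])]
    rng_plant.shuffle(classes)

    forbidden = [CCAAT_BOX.consensus, CCAAT_BOX.revcomp, GC_BOX.consensus, GC_BOX.revcomp]
    hw = config.window_halfwidth
    lo_clip, hi_clip = config.spacing_clip

    truth: list = []
    for idx, ((chrom, summit), cls) in enumerate(zip(placements, classes)):
        codes = chrom_codes[chrom]
        lo, hi = summit - hw, summit + hw
        _disrupt_region(codes, lo, hi, forbidden, rng_plant)

        motifs: list = []
        spacing: Optional[int] = None
        if cls in ("tandem_CCAAT", "both"):
            spacing = int(round(
                float(np.clip(rng_plant.normal(config.spacing_mean, config.spacing_sd),
                              lo_clip, hi_clip))
            ))
            s1 = summit - spacing // 2 - 2  # motif midpoints symmetric about summit
            s2 = s1 + spacing
            for s in (s1, s2):
                strand = "+" if rng_plant.random() < 0.5 else "-"
                text = CCAAT_BOX.consensus if strand == "+" else CCAAT_BOX.revcomp
                codes[s : s + 5] = _encode(text)
                motifs.append((s, strand, CCAAT_BOX.name))
        if cls in ("central_GC", "both"):
            s = summit - GC_BOX.length // 2
            strand = "+" if rng_plant.random() < 0.5 else "-"
            text = GC_BOX.consensus if strand == "+" else GC_BOX.revcomp
            codes[s : s + GC_BOX.length] = _encode(text)
            motifs.append((s, strand, GC_BOX.name))

        # planting may create chance occurrences straddling a motif edge
        protected = [(s, s + (5 if name == CCAAT_BOX.name else GC_BOX.length))
                     for s, _, name in motifs]
        _disrupt_region(codes, lo, hi, forbidden, rng_plant, protected=protected)

        cobound = cls in ("tandem_CCAAT", "both")
        enr_wt = config.enrichment_fold
        enr_ko = enr_wt / config.cofactor_dependency_fold if cobound else enr_wt
        truth.append(
            TruthPeak(f"peak{idx:04d}", cls, chrom, summit, tuple(motifs),
                      spacing, cobound, enr_wt, enr_ko)
        )

    genome = {chrom: _codes_to_str(codes) for chrom, codes in chrom_codes.items()}
    _verify_truth(genome, truth, hw)

    genes: list = []
    gi = 0
    for t in truth:
        if rng_genes.random() >= config.tss_fraction:
            continue
        tss = t.summit + int(rng_genes.integers(-200, 201))
        strand = "+" if rng_genes.random() < 0.5 else "-"
        if strand == "+":
            exons = (
                GenomicInterval(t.chrom, tss, tss + 300),
                GenomicInterval(t.chrom, tss + 500, tss + 800),
            )
        else:
            exons = (
                GenomicInterval(t.chrom, tss - 800, tss - 500),
                GenomicInterval(t.chrom, tss - 300, tss + 1),
            )
        genes.append(GeneModel(f"gene{gi:04d}", t.chrom, strand, tss, exons))
        gi += 1

    return SimulatedReference(genome, genes, truth, config)


def _verify_truth(genome: Mapping[str, str], truth: Sequence[TruthPeak], hw: int) -> None:
    """Assert the emitted genome carries exactly the planted motif hits."""
    for t in truth:
        window = genome[t.chrom][t.summit - hw : t.summit + hw]
        for motif in (CCAAT_BOX, GC_BOX):
            found = {(h.offset + t.summit - hw, h.strand)
                     for h in scan_consensus(window, motif)}
            planted = {(s, strand) for s, strand, name in t.motifs if name == motif.name}
            if found != planted:
                raise AssertionError(
                    f"{t.peak_id} ({t.cls}): {motif.name} hits {sorted(found)} "
                    f"!= planted {sorted(planted)}"
                )


def truth_frame(truth: Sequence[TruthPeak]):
    """Ground truth as a DataFrame (one row per planted peak)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "peak_id": [t.peak_id for t in truth],
            "class": [t.cls for t in truth],
            "chrom": [t.chrom for t in truth],
            "summit": [t.summit for t in truth],
            "spacing": [t.spacing for t in truth],
            "cobound": [t.cobound for t in truth],
            "enrichment_wt": [t.enrichment_wt for t in truth],
            "enrichment_ko": [t.enrichment_ko for t in truth],
            "motifs": [
                ";".join(f"{s}:{strand}:{name}" for s, strand, name in t.motifs) or "."
                for t in truth
            ],
        }
    )


def simulate_reads(
    ref: SimulatedReference,
    condition: str,
    seed_offset: int = 0,
) -> tuple:
    """Simulate single-end reads for one condition.

    Background fragments are uniform at ``background_depth`` reads/kb.
    Each peak contributes ``Poisson(enrichment * peak_read_scale)``
    fragments with midpoints ``Normal(summit, 1.5 * fragment_sd)``; in the
    ko condition the enrichment of co-bound peaks is attenuated by
    ``cofactor_dependency_fold`` and the control condition has no peak
    fragments at all.  Every fragment yields one read of ``read_length``
    bp from a uniformly chosen end, strand facing into the fragment.
    Returns ``(reads, LibraryStats)`` with the stats total equal to the
    emitted read count.  ``seed_offset`` selects an independent replicate.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    config = ref.config
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(_COND_KEY[condition], seed_offset))
    )

    reads: list = []
    for chrom in sorted(ref.genome):
        L = len(ref.genome[chrom])
        n_bg = rng.poisson(config.background_depth * L / 1000)
        mids = rng.uniform(0, L, n_bg)
        _emit_fragments(reads, rng, chrom, L, mids, config)

    if condition != "control":
        for t in ref.truth:
            enr = t.enrichment_ko if condition == "ko" else t.enrichment_wt
            n = rng.poisson(enr * config.peak_read_scale)
            L = len(ref.genome[t.chrom])
            mids = rng.normal(t.summit, 1.5 * config.fragment_sd, n)
            _emit_fragments(reads, rng, t.chrom, L, mids, config)

    reads.sort(key=lambda r: (r.chrom, r.pos5))
    return reads, LibraryStats(condition, len(reads))


def _emit_fragments(out, rng, chrom, L, mids, config) -> None:
    n = len(mids)
    if n == 0:
        return
    lens = np.clip(rng.normal(config.fragment_mean, config.fragment_sd, n),
                   config.read_length, None)
    starts = np.clip(np.round(mids - lens / 2).astype(np.int64), 0, L - 1)
    ends = np.clip(starts + lens.astype(np.int64), 1, L)
    left = rng.random(n) < 0.5
    for i in range(n):
        if left[i]:
            out.append(ReadAlignment(chrom, int(starts[i]), "+", config.read_length))
        else:
            out.append(ReadAlignment(chrom, int(ends[i] - 1), "-", config.read_length))


def candidate_peaks(
    ref: SimulatedReference,
    halfwidth: int = 150,
    jitter: int = 0,
    n_decoys: int = 0,
    source: str = "candidate",
) -> list:
    """Truth-derived candidate peak intervals, optionally jittered, plus
    background decoy intervals that a signal/background filter should
    reject."""
    config = ref.config
    rng = _rng(config, 3)
    peaks = []
    for t in ref.truth:
        shift = int(rng.integers(-jitter, jitter + 1)) if jitter else 0
        lo = max(0, t.summit - halfwidth + shift)
        hi = min(len(ref.genome[t.chrom]), t.summit + halfwidth + shift)
        peaks.append(Peak(GenomicInterval(t.chrom, lo, hi), name=t.peak_id, source=source))
    summits = {(t.chrom, t.summit) for t in ref.truth}
    placed = 0
    while placed < n_decoys:
        chrom = f"chr{int(rng.integers(0, config.n_chroms)) + 1}"
        pos = int(rng.integers(halfwidth, len(ref.genome[chrom]) - halfwidth))
        if any(c == chrom and abs(pos - s) < config.min_peak_spacing // 2
               for c, s in summits):
            continue
        peaks.append(
            Peak(GenomicInterval(chrom, pos - halfwidth, pos + halfwidth),
                 name=f"decoy{placed:03d}", source=source)
        )
        placed += 1
    return peaks


def synthesize_windows(
    n: int,
    planted_fraction: float = 1.0,
    spacing_mean: float = 35.0,
    spacing_sd: float = 5.0,
    spacing_clip: tuple = (30, 50),
    halfwidth: int = 150,
    gc_content: float = 0.40,
    seed: int = 0,
) -> list:
    """Standalone summit-centered windows with optional tandem CCAAT pairs.

    A fraction ``planted_fraction`` of the ``n`` windows carries a tandem
    CCAAT pair symmetric about the window center at a clipped-normal
    spacing; the rest carry no motif.  Spontaneous CCAAT occurrences are
    disrupted in all windows.  Returns a list of ``(sequence,
    planted_spacing_or_None)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    forbidden = [CCAAT_BOX.consensus, CCAAT_BOX.revcomp]
    lo_clip, hi_clip = spacing_clip
    out = []
    for i in range(n):
        codes = _random_codes(rng, 2 * halfwidth, gc_content)
        _disrupt_region(codes, 0, 2 * halfwidth, forbidden, rng)
        spacing = None
        if rng.random() < planted_fraction:
            spacing = int(round(float(np.clip(
                rng.normal(spacing_mean, spacing_sd), lo_clip, hi_clip))))
            center = halfwidth
            s1 = center - spacing // 2 - 2
            protected = []
            for s in (s1, s1 + spacing):
                strand = "+" if rng.random() < 0.5 else "-"
                text = CCAAT_BOX.consensus if strand == "+" else CCAAT_BOX.revcomp
                codes[s : s + 5] = _encode(text)
                protected.append((s, s + 5))
            _disrupt_region(codes, 0, 2 * halfwidth, forbidden, rng, protected=protected)
        out.append((_codes_to_str(codes), spacing))
    return out
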