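"""End-to-end orchestration: filter -> consensus/exclusion -> union/Venn ->
summit -> TSS annotation -> motif architecture -> differential occupancy.

The pipeline is declarative: a :class:`RunConfig` names the samples (reads
plus candidate peaks plus the control sample used for signal/background
filtering) and the analyses to run; :func:`run_pipeline` executes the
enabled stages, writes every intermediate table under ``outdir`` and
returns a :class:`ReportBundle`.  Given identical inputs and config the
outputs are byte-identical (no timestamps are written)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .differential import cobound_flags, compare_occupancy, stratify_by_cobinding
from .intervals import classify_location, merge_overlap_union, nearest_tss, overlap_filter, venn_counts
from .io import (
    open_genome,
    read_alignment_table,
    read_bed,
    read_gene_models,
    read_narrowpeak,
    write_narrowpeak,
    write_union_peaks,
    write_venn_table,
)
from .motifs import (
    CCAAT_BOX,
    GC_BOX,
    Motif,
    extract_windows,
    mode_separation,
    motif_content_summary,
    positional_profile,
    scan_consensus,
    summit_relative,
    tandem_pairs,
)
from .peaks import (
    FilterConfig,
    LibraryStats,
    annotate_counts,
    call_summits,
    filter_peaks,
    normalize_count,
    rank_top,
)

log = logging.getLogger(__name__)

__all__ = ["SampleSpec", "RunConfig", "ReportBundle", "run_pipeline"]

_MOTIFS = {"CCAAT": CCAAT_BOX, "GC": GC_BOX}


@dataclass
class SampleSpec:
    """One ChIP library: candidate peaks, reads and its control sample."""

    label: str
    reads: str
    peaks: Optional[str] = None
    control: Optional[str] = None  # label of the control sample


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    genome: Optional[str] = None
    gene_models: Optional[str] = None
    samples: list = field(default_factory=list)
    venn: list = field(default_factory=list)  # list of label lists
    consensus: list = field(default_factory=list)  # [query, reference] keep-filters
    exclusion: list = field(default_factory=list)  # [query, reference] drop-filters
    annotate: list = field(default_factory=list)  # labels to TSS-annotate
    motif_sets: list = field(default_factory=list)  # labels for motif analysis
    motif: str = "CCAAT"
    top_n: int = 600
    halfwidth: int = 150
    binwidth: int = 5
    smoothing_sigma: float = 5.0
    refine_summits: bool = True  # median-fragment-center anchoring for motif windows
    k_content: int = 2
    dmin: int = 30
    dmax: int = 50
    diff: Optional[dict] = None  # {a, b, peaks, cobound} labels
    filter: dict = field(default_factory=dict)  # FilterConfig overrides
    extension: int = 200
    tss_window: int = 500

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        samples = [SampleSpec(**s) for s in data.pop("samples", [])]
        return cls(samples=samples, **data)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(**self.filter)

    def motif_obj(self) -> Motif:
        if self.motif in _MOTIFS:
            return _MOTIFS[self.motif]
        return Motif(self.motif, self.motif)


@dataclass
class ReportBundle:
    sections: dict
    provenance: dict


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _read_peaks(path: str, source: str) -> list:
    if str(path).endswith(".narrowPeak"):
        return read_narrowpeak(path, source=source)
    return read_bed(path, source=source)


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the enabled stages and write all result tables.

    Unreadable inputs fail fast; per-peak problems (e.g. a peak on a
    chromosome missing from the genome) accumulate as error records in
    the ``errors`` section without aborting the run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sections: dict = {}
    errors: list = []

    labels = [s.label for s in config.samples]
    if len(set(labels)) != len(labels):
        raise ValueError("sample labels must be unique")
    by_label = {s.label: s for s in config.samples}
    for s in config.samples:
        for path in (s.reads, s.peaks):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"sample {s.label}: missing input {path}")

    reads = {s.label: read_alignment_table(s.reads) for s in config.samples}
    stats = {lab: LibraryStats(lab, max(len(r), 1)) for lab, r in reads.items()}
    genes = read_gene_models(config.gene_models) if config.gene_models else []
    genome = open_genome(config.genome) if config.genome else None

    # --- filter + summit stage --------------------------------------------
    fconf = config.filter_config()
    filtered: dict = {}
    for s in config.samples:
        if s.peaks is None:
            continue
        cands = _read_peaks(s.peaks, s.label)
        cands = annotate_counts(cands, reads[s.label], config.extension, target="raw")
        if s.control is not None:
            if s.control not in by_label:
                raise ValueError(f"sample {s.label}: undeclared control {s.control!r}")
            cands = annotate_counts(cands, reads[s.control], config.extension, target="control")
            kept = filter_peaks(cands, stats[s.label], stats[s.control], fconf)
        else:
            kept = [
                dataclasses.replace(
                    p,
                    norm_count=normalize_count(
                        p.raw_count, stats[s.label].total_unique_reads, fconf.norm_scale
                    ),
                )
                for p in cands
            ]
        kept = call_summits(kept, reads[s.label], config.extension)
        filtered[s.label] = kept
        write_narrowpeak(kept, outdir / f"filtered_{s.label}.narrowPeak")
        log.info("stage=filter sample=%s in=%d out=%d", s.label, len(cands), len(kept))
    sections["filtered"] = {lab: len(p) for lab, p in filtered.items()}

    # --- consensus / exclusion --------------------------------------------
    for query, reference in config.consensus:
        filtered[query] = overlap_filter(filtered[query], filtered[reference], mode="keep")
        log.info("stage=consensus query=%s ref=%s out=%d", query, reference, len(filtered[query]))
    for query, reference in config.exclusion:
        filtered[query] = overlap_filter(filtered[query], filtered[reference], mode="drop")
        log.info("stage=exclusion query=%s ref=%s out=%d", query, reference, len(filtered[query]))

    # --- union / Venn ------------------------------------------------------
    venn_section = {}
    for i, comparison in enumerate(config.venn):
        union = merge_overlap_union({lab: filtered[lab] for lab in comparison})
        tag = "_".join(comparison)
        write_union_peaks(union, outdir / f"union_{tag}.bed")
        write_venn_table(union, outdir / f"venn_{tag}.tsv")
        venn_section[tag] = venn_counts(union)
        log.info("stage=venn sets=%s unions=%d", tag, len(union))
    sections["venn"] = venn_section

    # --- TSS annotation ----------------------------------------------------
    annot_section = {}
    for lab in config.annotate:
        rows = []
        for p in filtered.get(lab, []):
            gid, dist = nearest_tss(p, genes) if genes else (None, None)
            loc = classify_location(p, genes, config.tss_window) if genes else "intergenic"
            rows.append({"peak_id": p.id, "chrom": p.interval.chrom,
                         "start": p.interval.start, "end": p.interval.end,
                         "summit": p.summit, "gene_id": gid,
                         "tss_distance": dist, "location": loc})
        df = pd.DataFrame(rows)
        df.to_csv(outdir / f"annotation_{lab}.tsv", sep="\t", index=False)
        if len(df):
            annot_section[lab] = df["location"].value_counts().to_dict()
        else:
            annot_section[lab] = {}
        log.info("stage=annotate sample=%s peaks=%d", lab, len(rows))
    sections["annotation"] = annot_section

    # --- motif architecture ------------------------------------------------
    motif_section = {}
    if config.motif_sets and genome is not None:
        motif = config.motif_obj()
        for lab in config.motif_sets:
            top = rank_top(filtered[lab], config.top_n)
            if config.refine_summits:
                top = call_summits(top, reads[lab], config.extension, refine=True)
            windows, errs = extract_windows(top, genome, config.halfwidth)
            errors.extend(errs)
            frac, counts = motif_content_summary(windows, motif, config.k_content)
            hit_rows = []
            hit_sets = []
            n_tandem = 0
            for w in windows:
                hits = summit_relative(scan_consensus(w.seq, motif), w)
                hit_sets.append(hits)
                if tandem_pairs(hits, config.dmin, config.dmax):
                    n_tandem += 1
                hit_rows.extend(
                    {"peak_id": w.peak_id, "offset": h.offset, "strand": h.strand}
                    for h in hits
                )
            profile = positional_profile(hit_sets, config.halfwidth,
                                         config.binwidth, config.smoothing_sigma)
            sep = mode_separation(profile)
            tandem_frac = n_tandem / len(windows) if windows else None
            pd.DataFrame(hit_rows).to_csv(outdir / f"motif_hits_{lab}.tsv", sep="\t", index=False)
            pd.DataFrame({
                "bin_center": profile.bin_centers,
                "raw_count": profile.counts,
                "smoothed": profile.smoothed,
            }).to_csv(outdir / f"motif_profile_{lab}.tsv", sep="\t", index=False)
            motif_section[lab] = {
                "n_windows": len(windows),
                "frac_ge_k": frac,
                "frac_tandem": tandem_frac,
                "mode_separation": sep,
            }
            log.info("stage=motifs sample=%s windows=%d", lab, len(windows))
        pd.DataFrame([
            {"set": lab, **vals} for lab, vals in motif_section.items()
        ]).to_csv(outdir / "motif_summary.tsv", sep="\t", index=False)
    sections["motifs"] = motif_section

    # --- differential occupancy -------------------------------------------
    if config.diff:
        d = config.diff
        ref_peaks = filtered[d["peaks"]]
        cobound_ref = filtered[d["cobound"]] if d.get("cobound") in filtered else (
            _read_peaks(d["cobound"], "cobound") if d.get("cobound") else []
        )
        flags = cobound_flags(ref_peaks, cobound_ref)
        comparisons = compare_occupancy(
            ref_peaks, reads[d["a"]], stats[d["a"]], reads[d["b"]], stats[d["b"]],
            flags, config.extension,
        )
        per_peak, summaries = stratify_by_cobinding(comparisons)
        per_peak.to_csv(outdir / "occupancy_comparison.tsv", sep="\t", index=False)
        pd.DataFrame([
            {"group": g, **vals} for g, vals in summaries.items()
        ]).to_csv(outdir / "occupancy_summary.tsv", sep="\t", index=False)
        sections["differential"] = summaries
        log.info("stage=diff peaks=%d", len(ref_peaks))

    sections["errors"] = errors
    provenance = {
        "config_hash": _config_hash(config),
        "version": __version__,
        "seed": config.seed,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return ReportBundle(sections, provenance)
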