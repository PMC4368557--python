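# chiparch

Integration analysis for transcription-factor ChIP-seq peak sets, built
around the promoter architecture of the Sp-family / Nf-y regulatory
system: Sp1 and Sp3 bind GC boxes (`GGGCGGG`), while Sp2 and the
heterotrimeric factor Nf-y occupy CCAAT boxes (`CCAAT`/`ATTGG`) that are
frequently arranged in tandem ~35 bp apart.  The package is a library
(plus a thin `chiparch` CLI) for epigenomics analysts who have candidate
peaks from a peak caller and want the downstream integration steps as
tested, reusable code:

- **Peak filtering against controls** — extended-read tag counts,
  depth normalization to a fixed library size, and retention of peaks
  with ≥ 30 raw reads and a ≥ 3-fold normalized signal-to-background
  ratio over an IgG or knockout-cell control.
- **Union/Venn overlap classification** — merge labelled peak sets
  wherever intervals share ≥ 1 bp and assign each union peak its
  membership signature; two-antibody consensus (keep) and
  knockout-exclusion (drop) filters.
- **Summit calling** — reads extended to 200 bp fragment length; the
  summit is the position of highest extended-read overlap.
- **TSS annotation** — nearest-TSS signed distances and
  TSS / intragenic / intergenic classification (±500 bp window).
- **Motif architecture** — IUPAC consensus scanning on both strands,
  fraction of summit windows (±150 bp) with ≥ *k* perfect motifs,
  tandem pairs at 30–50 nt start-to-start spacing, and summit-relative
  positional profiles with bimodal mode separation.
- **Differential occupancy** — wt/ko ratios of normalized tag counts at
  fixed peak coordinates, stratified by co-binding with a second factor.
- **Synthetic data with planted truth** — a seeded simulator emitting a
  toy genome, gene models, peaks of four motif-architecture classes
  (tandem CCAAT / central GC box / both / none), and two-condition
  single-end reads in which co-bound peaks lose 3-fold enrichment in the
  knockout, so every stage is testable without downloads.

## Core quantities

For a peak with raw tag count *r* in a library of *N* uniquely aligned
reads, the normalized count is *n = r · s / N* (default scale
*s* = 10⁶). A peak is retained when *r* ≥ 30 and *n*/*n*₍ctrl₎ ≥ 3, with
the control count floored at one read. Occupancy change between
conditions *a* and *b* is the pseudocounted ratio
(*nₐ* + ½)/(*n_b* + ½). Motif positional enrichment is the histogram of
match midpoints relative to peak summits; for a bimodal profile the
reported separation is the distance between the most prominent mode on
each side of the summit (Gaussian-smoothed, parabolically refined) — for
tandem CCAAT promoters this recovers the planted ~35 bp spacing.

## Worked example

`examples/` contains one narrative script per capability.
`examples/04_differential_occupancy.py` simulates wild-type and knockout
libraries over 200 planted peaks and prints:

```
cobound      n=100  median wt/ko ratio 2.61  attenuated 0.88  potentiated 0.00
not_cobound  n=100  median wt/ko ratio 0.97  attenuated 0.00  potentiated 0.00
```

The 100 co-bound peaks (tandem-CCAAT classes) were simulated with
3-fold-attenuated enrichment in the knockout; the measured median ratio
of 2.61 reflects that attenuation diluted by the background reads under
each peak, while non-co-bound peaks stay at ~1.
`examples/03_motif_architecture.py` plants tandem CCAAT pairs in 80% of
600 windows and recovers the fraction (0.780 measured vs 0.780 planted)
and the spacing (35.5 bp mode separation vs 35.7 bp planted mean).

The same stages run from the shell:

```sh
chiparch simulate --out sim --seed 7
chiparch filter --peaks sim/candidates.bed --reads sim/reads_wt.tsv \
    --control-reads sim/reads_control.tsv --out filtered.narrowPeak
chiparch motifs --peaks filtered.narrowPeak --genome sim/genome.fa \
    --motif CCAAT --top 600 --out profile.tsv
```

## Limitations

Read alignment and peak calling proper are out of scope (candidate peaks
and alignments are consumed, not produced), as are position-weight-matrix
scoring, *de novo* motif discovery and count-model significance testing.
See `docs/methods.md` for the model, parameter and design notes.
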