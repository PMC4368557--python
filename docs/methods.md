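# Methods notes

## Scope and model

`chiparch` implements the downstream integration stages of a
transcription-factor ChIP-seq study: candidate peaks (from any peak
caller) and aligned single-end reads go in; filtered peak sets, overlap
(Venn) classifications, summits, TSS annotation, canonical-motif
architecture statistics and two-condition occupancy comparisons come
out.  The biological system it targets is the Sp/Nf-y promoter
architecture — GC boxes (`GGGCGGG`) bound by Sp1/Sp3 zinc fingers and
CCAAT boxes (`CCAAT`/`ATTGG`) bound by the Nf-y trimer, with tandem
CCAAT pairs ~35 bp apart marking sites where Sp2 and Nf-y co-bind and
depend on each other — but every operation is generic over motifs and
factors.

Coordinates are 0-based half-open everywhere; two intervals overlap iff
they share at least one base (`a.start < b.end and b.start < a.end`), so
book-ended intervals do not overlap.  One-based tabular peak input is
converted on read (start − 1); BED and narrowPeak are taken as-is.

## Peak processing

**Tag counts.** A read counts toward a peak when its fragment-extended
span overlaps the peak by ≥ 1 bp.  Extension takes each read to a total
length of 200 bp from its 5′ end in its strand direction — i.e. to the
typical sonicated fragment length, not 200 bp appended to the read; the
extension length is configurable.  Counts are recomputed from the
alignments rather than taken from the peak caller.

**Normalization and filtering.** Normalized count = raw × scale /
library-total, scale defaulting to 10⁶ unique reads (2×10⁷ is a common
alternative for scatter plots; the filter uses a ratio and is
scale-free).  A peak survives when raw ≥ `min_raw` (30) and the
normalized treatment/control ratio is ≥ `min_ratio` (3), with control
counts floored at one read before normalization so knockout/IgG windows
with zero reads do not divide by zero.  Both thresholds are monotone:
raising either can only shrink the surviving set.

**Summits.** Coverage is evaluated on segments delimited by the
boundaries of the extended reads (clipped to the peak); the summit is
the floor midpoint of the leftmost maximal-coverage segment.  Splitting
at every read boundary without merging equal-coverage neighbours makes
the tie-break deterministic: two abutting single-read spans yield the
left span's midpoint, not the midpoint of their union.

**Summit anchoring for motif analysis.** When nearly all of a peak's
fragments overlap one another (narrow fragment-position scatter relative
to the 200 bp extension), the maximal-coverage segment spans the
intersection of the outermost fragments, making the pileup summit a
midrange estimator whose error (~10 bp median on the default simulation)
blurs a 35 bp bimodal motif profile visibly inward.  The pipeline's
motif stage therefore offers `refine_summits` (default on): windows are
re-anchored at the median extended-fragment center of the reads in the
peak (~3 bp median error), while the pileup summit remains the reported,
oracle-tested summit definition.

## Motif architecture

Scanning is exact IUPAC consensus matching on both strands (the reverse
complement reported as strand `−` at the match's lowest coordinate),
overlapping matches included, `N` in the sequence never matching.
Palindromic consensi are scanned once to avoid sequence-identical
duplicates.  Content is summarized as the fraction of summit windows
(±150 bp) with ≥ *k* hits (*k* = 2 by default).  Tandem pairs are
unordered hit pairs at start-to-start distance within [30, 50] nt,
inclusive; start-to-start is the only distance metric consistent with a
"~35 bp mean distance" for pairs planted 35 bp apart.

The positional profile histograms match midpoints relative to the
summit.  Bin width defaults to 5 bp with 5 bp Gaussian smoothing for
mode detection (raw counts are preserved).  A 10 bp grid was rejected
because it cannot localize the narrow CCAAT modes: on noise-free windows
it reports ~31 bp for a planted 35.3 bp separation purely through bin
quantization, while 5 bp bins recover 35.1 bp.  Mode separation finds
smoothed local maxima with prominence ≥ 10% of the global maximum,
refines each by parabolic interpolation, and reports the distance
between the most prominent mode on each side of the summit; unimodal or
empty profiles return "undefined" rather than a number.  This is a
positional-density summary, not a central-enrichment significance test —
no binomial p-value is computed.

## TSS annotation

Distances are measured from the summit (interval midpoint when no summit
is set) to the nearest TSS on the same chromosome, signed positive
downstream in the gene's orientation; ties break toward the smaller TSS
coordinate, then lexicographic gene id.  Classification is TSS when
|distance| ≤ 500 bp (configurable), else intragenic when the anchor lies
in a gene span, else intergenic.  Chromosomes without genes annotate as
missing/intergenic instead of raising.

## Differential occupancy

Counts are evaluated at the reference-condition (wild-type) peak
coordinates in both libraries, depth-normalized, and compared as
(nₐ + c)/(n_b + c) with pseudocount c = 0.5 so knockout-absent sites stay
finite; double-zero sites report 1.  Peaks are stratified by co-binding
(≥ 1 bp overlap with the second factor's peak set), and each group gets
n, median ratio, and the fractions beyond a configurable 2-fold cutoff
("attenuated" / "potentiated"); the continuous ratio is always reported
alongside the label.  No dispersion model or p-value is attached — the
comparison is deliberately ratio-only.

## Synthetic data generator

The generator emulates the study design, not sequencing chemistry: i.i.d.
40% GC background, no sequencing errors, no mappability or duplicate
structure.  Defaults (the conditions used throughout the tests and the
acceptance script): 2 chromosomes × 5 Mb, 200 peaks (50 per class:
tandem CCAAT / central GC / both / none) spaced ≥ 5 kb apart, tandem
spacing ~ Normal(35, 5) clamped to [30, 50] nt, enrichment 10-fold over
background, knockout attenuation 3-fold at co-bound (tandem-carrying)
peaks, fragments ~ Normal(200, 20) bp, 50 bp single-end reads,
background 10 reads/kb, and an expected 10 × 10 = 100 fragments per peak
(`enrichment_fold × peak_read_scale`).  These sizes keep the fraction of
reads in peaks near 15%, leave the ≥ 30-raw-read filter a comfortable
margin (~105 expected reads per candidate), and keep background under a
peak small relative to the attenuated knockout signal.  A `control`
condition contains background only and plays the IgG/input role.

Before planting, every spontaneous CCAAT/GC-box occurrence within
±150 bp of a summit is disrupted by single-base substitution (rescanning
until clean), so a scan of the emitted genome finds exactly the planted
hits — this is verified at generation time and is a deliberate bias:
background is motif-depleted near summits only.  Planted pairs are
symmetric about the summit; each motif takes a random strand.  A TSS is
placed within ±200 bp of 90% of summits.  Candidate peaks are
truth-derived (±150 bp, optionally jittered) plus background decoys that
the filter should reject.  All randomness flows from one master seed
through named substreams, so identical configurations are byte-identical
and conditions/replicates are independent.

Because co-bound peaks sit on ~5 background reads, the measured median
wt/ko ratio at co-bound sites is ~2.6 rather than the planted 3.0 — the
attenuation is diluted by background under the peak exactly as in real
data; the Monte-Carlo tests confirm the underlying fragment rates match
the configured 3-fold attenuation.  What passing tests show is that the
pipeline recovers planted architecture under these idealized conditions;
they do not certify behaviour under real-genome repeat structure,
chromatin-dependent background, or imperfect motif matches.

## Numerical and degenerate-input choices

- Ranking ties (equal normalized counts) break by (chromosome, start).
- Empty window lists report fractions as missing (`None`), not 0.
- Windows truncated at chromosome ends keep their actual bounds.
- Missing chromosomes or summits during window extraction become
  per-peak error records; the pipeline accumulates them without
  aborting, but unreadable input files fail fast.
- Profile midpoints are clipped into [−halfwidth, halfwidth) so the raw
  histogram always sums to the number of hits.
- Pipeline outputs carry no timestamps; rerunning an identical
  configuration produces byte-identical tables.
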