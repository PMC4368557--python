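"""Union/Venn classification of labelled peak sets.

Builds three small peak sets, merges every interval that shares at least
one base into union peaks, and tabulates Venn cell counts by membership
signature — the operation behind multi-antibody overlap diagrams.
"""

import chiparch as ca


def peaks(intervals):
    return [ca.Peak(ca.GenomicInterval("chr1", s, e)) for s, e in intervals]


sets = {
    "Sp1_ab1": peaks([(100, 300), (1000, 1200), (5000, 5400)]),
    "Sp1_ab2": peaks([(150, 350), (1100, 1250), (8000, 8200)]),
    "Sp2": peaks([(5100, 5300), (9000, 9100)]),
}

union = ca.merge_overlap_union(sets)
print(f"{len(union)} union peaks from "
      f"{sum(len(v) for v in sets.values())} input peaks")
for up in union:
    print(f"  {up.interval.chrom}:{up.interval.start}-{up.interval.end}  "
          f"bound by {up.signature}")

print("\nVenn cell counts (peaks per membership signature):")
for sig, n in sorted(ca.venn_counts(union).items()):
    print(f"  {sig:<18} {n}")

# consensus: keep only antibody-1 peaks confirmed by antibody-2
consensus = ca.overlap_filter(sets["Sp1_ab1"], sets["Sp1_ab2"], mode="keep")
print(f"\ntwo-antibody consensus: {len(consensus)}/{len(sets['Sp1_ab1'])} "
      "Sp1_ab1 peaks confirmed by Sp1_ab2")
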