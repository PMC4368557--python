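"""Wild-type vs knockout differential occupancy at fixed peak positions.

In the simulation, peaks carrying tandem CCAAT motifs are "co-bound" by a
second factor; knocking that factor out attenuates their enrichment
3-fold while other peaks are untouched.  Comparing depth-normalized tag
counts at the wild-type peak coordinates separates the two groups by
their wt/ko ratio.
"""

import chiparch as ca

ref = ca.generate_reference(ca.SimConfig(seed=3))
wt, st_wt = ca.simulate_reads(ref, "wt")
ko, st_ko = ca.simulate_reads(ref, "ko")

peaks = ca.candidate_peaks(ref)
tmap = {t.peak_id: t for t in ref.truth}
flags = [tmap[p.name].cobound for p in peaks]

comparisons = ca.compare_occupancy(peaks, wt, st_wt, ko, st_ko, flags)
per_peak, summaries = ca.stratify_by_cobinding(comparisons, fold_threshold=2.0)

for group, s in summaries.items():
    print(f"{group:<12} n={s['n']:3d}  median wt/ko ratio {s['median_ratio']:.2f}  "
          f"attenuated {s['frac_attenuated']:.2f}  potentiated {s['frac_potentiated']:.2f}")
print("\nco-bound sites lose ~3-fold occupancy in the knockout (ratio >> 1),")
print("non-co-bound sites are unchanged (ratio ~ 1) — the co-dependency signature.")
print("\nfirst rows of the per-peak table:")
print(per_peak.head(5).to_string(index=False))
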