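"""Consensus scanning, motif content, tandem spacing and positional
profiles, validated against naive string-comparison oracles and
parameter-recovery on synthetic windows."""

import numpy as np
import pytest

import chiparch as ca
from chiparch.motifs import Window, _IUPAC

COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}


def naive_scan(sequence, consensus):
    """Sliding-window two-strand oracle with explicit IUPAC comparison."""
    seq = sequence.upper()
    rc = "".join(COMP[c] for c in reversed(consensus))
    hits = []

    def matches(s, pattern):
        return all(base in _IUPAC[p] for base, p in zip(s, pattern))

    for i in range(len(seq) - len(consensus) + 1):
        window = seq[i : i + len(consensus)]
        if matches(window, consensus):
            hits.append((i, "+"))
    if rc != consensus:
        for i in range(len(seq) - len(consensus) + 1):
            window = seq[i : i + len(consensus)]
            if matches(window, rc):
                hits.append((i, "-"))
    return sorted(hits)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestScanConsensus:
    def test_forward_hit(self):
        hits = ca.scan_consensus("AACCAATAA", ca.CCAAT_BOX)
        assert [(h.offset, h.strand) for h in hits] == [(2, "+")]

    def test_reverse_complement_hit(self):
        hits = ca.scan_consensus("AATTGGAA", ca.CCAAT_BOX)
        assert [(h.offset, h.strand) for h in hits] == [(1, "-")]

    def test_overlapping_hits_all_reported(self):
        hits = ca.scan_consensus("CCAATCCAATT", ca.CCAAT_BOX)
        offsets = {(h.offset, h.strand) for h in hits}
        assert (0, "+") in offsets and (5, "+") in offsets

    def test_n_in_sequence_never_matches(self):
        assert ca.scan_consensus("CCNAT", ca.CCAAT_BOX) == []

    def test_n_in_consensus_matches_any_base(self):
        m = ca.Motif("any", "CCNAT")
        assert [h.offset for h in ca.scan_consensus("ACCGATA", m) if h.strand == "+"] == [1]

    def test_palindromic_consensus_not_double_counted(self):
        m = ca.Motif("pal", "ACGT")
        hits = ca.scan_consensus("AACGTA", m)
        assert [(h.offset, h.strand) for h in hits] == [(1, "+")]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 300)
        for motif in (ca.CCAAT_BOX, ca.GC_BOX):
            got = [(h.offset, h.strand) for h in ca.scan_consensus(seq, motif)]
            assert got == naive_scan(seq, motif.consensus)

    @pytest.mark.parametrize("seed", range(10))
    def test_revcomp_symmetry(self, seed):
        """Scanning the reverse complement yields the mirrored hit list
        with strands swapped."""
        rng = np.random.default_rng(1000 + seed)
        seq = random_seq(rng, 200)
        rc = "".join(COMP[c] for c in reversed(seq))
        fwd = {(h.offset, h.strand) for h in ca.scan_consensus(seq, ca.CCAAT_BOX)}
        rev = {
            (len(seq) - h.offset - h.length, "+" if h.strand == "-" else "-")
            for h in ca.scan_consensus(rc, ca.CCAAT_BOX)
        }
        assert fwd == rev


class TestExtractWindows:
    def _genome(self):
        return {"chr1": "A" * 1000}

    def test_window_bounds(self):
        p = ca.Peak(ca.GenomicInterval("chr1", 100, 300), name="p", summit=200)
        windows, errors = ca.extract_windows([p], self._genome(), 150)
        assert not errors
        (w,) = windows
        assert (w.start, w.end, len(w.seq)) == (50, 350, 300)

    def test_left_truncated_window(self):
        p = ca.Peak(ca.GenomicInterval("chr1", 50, 200), name="p", summit=100)
        (w,), _ = ca.extract_windows([p], self._genome(), 150)
        assert (w.start, w.end, len(w.seq)) == (0, 250, 250)

    def test_missing_chromosome_is_error_record(self):
        p = ca.Peak(ca.GenomicInterval("chrX", 100, 300), name="p", summit=200)
        windows, errors = ca.extract_windows([p], self._genome(), 150)
        assert windows == [] and len(errors) == 1 and "chrX" in errors[0]["error"]

    def test_missing_summit_is_error_record(self):
        p = ca.Peak(ca.GenomicInterval("chr1", 100, 300), name="p")
        windows, errors = ca.extract_windows([p], self._genome(), 150)
        assert windows == [] and "summit" in errors[0]["error"]


class TestMotifContent:
    def _window(self, seq, pid="w"):
        return Window(pid, "chr1", 0, len(seq), len(seq) // 2, seq)

    def test_fraction_with_planted_counts(self):
        pad = "T" * 10
        seqs = {
            "w0": pad * 6,
            "w1": pad + "CCAAT" + pad * 4,
            "w2": pad + "CCAAT" + pad + "CCAAT" + pad * 2,
            "w3": pad + "ATTGG" + pad + "CCAAT" + pad * 2,
            "w4": pad + "CCAAT" + pad + "CCAAT" + pad + "CCAAT",
        }
        windows = [self._window(s, pid) for pid, s in seqs.items()]
        frac, counts = ca.motif_content_summary(windows, ca.CCAAT_BOX, k=2)
        assert [counts[f"w{i}"] for i in range(5)] == [0, 1, 2, 2, 3]
        assert frac == pytest.approx(0.6)

    def test_all_a_window_zero_hits(self):
        frac, counts = ca.motif_content_summary([self._window("A" * 50)], ca.CCAAT_BOX)
        assert counts["w"] == 0 and frac == 0.0

    def test_empty_window_list_undefined(self):
        frac, counts = ca.motif_content_summary([], ca.CCAAT_BOX)
        assert frac is None and counts == {}

    def test_fraction_non_increasing_in_k(self):
        rng = np.random.default_rng(7)
        windows = [self._window(random_seq(rng, 300), f"w{i}") for i in range(50)]
        fracs = [ca.motif_content_summary(windows, ca.CCAAT_BOX, k)[0] for k in (1, 2, 3, 4)]
        assert fracs == sorted(fracs, reverse=True)


class TestTandemPairs:
    def _hits(self, offsets):
        return [ca.MotifHit(o, "+", 5) for o in offsets]

    def test_pair_at_40(self):
        pairs = ca.tandem_pairs(self._hits([100, 140]))
        assert len(pairs) == 1
        a, b = pairs[0]
        assert b.offset - a.offset == 40

    def test_single_hit_no_pairs(self):
        assert ca.tandem_pairs(self._hits([10])) == []

    def test_boundary_distances(self):
        pairs = ca.tandem_pairs(self._hits([0, 29, 60]))
        assert [(a.offset, b.offset) for a, b in pairs] == [(29, 60)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        hits = self._hits(sorted(int(x) for x in rng.integers(0, 300, size=12)))
        got = {(a.offset, b.offset) for a, b in ca.tandem_pairs(hits)}
        expected = {
            (min(h1.offset, h2.offset), max(h1.offset, h2.offset))
            for i, h1 in enumerate(hits)
            for h2 in hits[i + 1 :]
            if 30 <= abs(h1.offset - h2.offset) <= 50
        }
        assert got == expected


class TestPositionalProfile:
    def test_empty_profile(self):
        prof = ca.positional_profile([[], []], halfwidth=150)
        assert prof.counts.sum() == 0 and ca.mode_separation(prof) is None

    def test_single_position_mass(self):
        hits = [[ca.MotifHit(15, "+", 5)]] * 10  # midpoints at +17
        prof = ca.positional_profile(hits, halfwidth=150, binwidth=10)
        assert prof.counts.sum() == 10
        assert prof.counts[np.argmax(prof.counts)] == 10
        center = prof.bin_centers[np.argmax(prof.counts)]
        assert abs(center - 17) <= 5

    def test_symmetric_input_gives_symmetric_profile(self):
        hits = []
        for x in (25, 45, 65):  # bin-center offsets so mirroring is exact
            hits.append([ca.MotifHit(x - 2, "+", 5), ca.MotifHit(-x - 2, "+", 5)])
        prof = ca.positional_profile(hits, halfwidth=100, binwidth=10)
        assert np.allclose(prof.counts, prof.counts[::-1])

    def test_counts_sum_and_summit_shift_invariance(self):
        rng = np.random.default_rng(2)
        base = [[ca.MotifHit(int(o), "+", 5) for o in rng.integers(-140, 140, size=3)]
                for _ in range(20)]
        prof = ca.positional_profile(base, halfwidth=150)
        assert prof.counts.sum() == sum(len(h) for h in base)
        # offsets are summit-relative, so a shared summit shift is a no-op
        prof2 = ca.positional_profile(list(base), halfwidth=150)
        assert np.array_equal(prof.counts, prof2.counts)


class TestModeSeparation:
    def test_planted_modes_at_minus18_plus17(self):
        """Two Gaussian bumps centered at -18 and +17 separate by 35."""
        centers = np.arange(-148, 150, 4) + 0.0
        y = np.exp(-0.5 * ((centers + 18) / 6) ** 2) + np.exp(-0.5 * ((centers - 17) / 6) ** 2)
        prof = ca.PositionalProfile(150, 4, y * 100, y * 100, n_sequences=1)
        sep = ca.mode_separation(prof)
        assert sep == pytest.approx(35, abs=1.5)

    def test_unimodal_central_undefined(self):
        centers = np.arange(-148, 150, 4) + 0.0
        y = np.exp(-0.5 * (centers / 10) ** 2)
        prof = ca.PositionalProfile(150, 4, y * 100, y * 100, n_sequences=1)
        assert ca.mode_separation(prof) is None

    def test_recovery_from_synthetic_windows(self):
        """On 600 windows with tandem CCAAT pairs planted at clipped-normal
        spacing, mode separation recovers the realized mean spacing within
        2 bp and the tandem fraction recovers the planted fraction within
        0.05."""
        wins = ca.synthesize_windows(600, planted_fraction=0.8, seed=5)
        hit_sets = []
        n_tandem = 0
        for seq, _ in wins:
            hits = [ca.MotifHit(h.offset - 150, h.strand, h.length)
                    for h in ca.scan_consensus(seq, ca.CCAAT_BOX)]
            hit_sets.append(hits)
            if ca.tandem_pairs(hits):
                n_tandem += 1
        planted = [s for _, s in wins if s is not None]
        frac_planted = len(planted) / len(wins)
        assert n_tandem / len(wins) == pytest.approx(frac_planted, abs=0.05)
        prof = ca.positional_profile(hit_sets, halfwidth=150)
        sep = ca.mode_separation(prof)
        assert sep == pytest.approx(np.mean(planted), abs=2.0)


def test_motif_validation():
    with pytest.raises(ValueError):
        ca.Motif("bad", "CCAAX")
    with pytest.raises(ValueError):
        ca.Motif("empty", "")
    assert ca.GC_BOX.revcomp == "CCCGCCC"
    assert ca.GC_BOX_LONG.consensus == "GGGGCGGGG"
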