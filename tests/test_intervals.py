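"""Interval algebra: union/Venn construction, overlap filtering and
TSS annotation, checked against per-base brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chiparch as ca
from chiparch.intervals import venn_counts

from conftest import random_peaks


def brute_force_union(peak_sets):
    """Connected-components oracle: exhaustively link every pair of
    intervals sharing >=1 base (transitive closure), then report each
    component's span and contributing labels."""
    items = [
        (p.interval.chrom, p.interval.start, p.interval.end, label)
        for label, peaks in peak_sets.items()
        for p in peaks
    ]
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei, _ = items[i]
            cj, sj, ej, _ = items[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    comps = {}
    for i, (chrom, s, e, label) in enumerate(items):
        root = find(i)
        c = comps.setdefault(root, [chrom, s, e, set()])
        c[1], c[2] = min(c[1], s), max(c[2], e)
        c[3].add(label)
    return sorted(
        (chrom, s, e, frozenset(labels)) for chrom, s, e, labels in comps.values()
    )


def covered_bases(intervals):
    return {(iv.chrom, b) for iv in intervals for b in range(iv.start, iv.end)}


def brute_force_overlaps(a, b):
    ia, ib = a.interval, b.interval
    return ia.chrom == ib.chrom and ia.start < ib.end and ib.start < ia.end


class TestMergeOverlapUnion:
    def test_single_set_identity(self):
        peaks = [ca.Peak(ca.GenomicInterval("chr1", 100, 200))]
        (up,) = ca.merge_overlap_union({"A": peaks})
        assert (up.interval.start, up.interval.end) == (100, 200)
        assert up.membership == frozenset({"A"})

    def test_three_sets_example(self):
        sets = {
            "A": [ca.Peak(ca.GenomicInterval("chr1", 100, 200))],
            "B": [ca.Peak(ca.GenomicInterval("chr1", 150, 250))],
            "C": [ca.Peak(ca.GenomicInterval("chr1", 300, 400))],
        }
        result = ca.merge_overlap_union(sets)
        got = [(u.interval.start, u.interval.end, set(u.membership)) for u in result]
        assert got == [(100, 250, {"A", "B"}), (300, 400, {"C"})]

    def test_book_ended_intervals_not_merged(self):
        sets = {
            "A": [ca.Peak(ca.GenomicInterval("chr1", 0, 10))],
            "B": [ca.Peak(ca.GenomicInterval("chr1", 10, 20))],
        }
        assert len(ca.merge_overlap_union(sets)) == 2

    def test_duplicate_labels_rejected(self):
        pair = [("A", []), ("A", [])]
        with pytest.raises(ValueError, match="duplicate"):
            ca.merge_overlap_union(pair)

    def test_idempotent_self_merge(self):
        rng = np.random.default_rng(5)
        peaks = random_peaks(rng, 20)
        once = ca.merge_overlap_union({"A": peaks})
        twice = ca.merge_overlap_union(
            {"A": [ca.Peak(u.interval) for u in once]}
        )
        assert [u.interval for u in once] == [u.interval for u in twice]
        assert all(u.membership == frozenset({"A"}) for u in twice)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_per_base_oracle(self, seed):
        """Union intervals, base coverage and membership all agree with the
        brute-force component/coverage oracles on randomized instances."""
        rng = np.random.default_rng(seed)
        sets = {
            label: random_peaks(rng, int(rng.integers(1, 15)), max_pos=3000, max_len=300)
            for label in "ABC"[: int(rng.integers(1, 4))]
        }
        result = ca.merge_overlap_union(sets)
        got = [
            (u.interval.chrom, u.interval.start, u.interval.end, u.membership)
            for u in result
        ]
        assert got == brute_force_union(sets)
        # base conservation: output covers exactly the union of input bases
        inputs = [p.interval for peaks in sets.values() for p in peaks]
        assert covered_bases([u.interval for u in result]) == covered_bases(inputs)

    def test_output_sorted_non_overlapping(self):
        rng = np.random.default_rng(42)
        sets = {"A": random_peaks(rng, 30), "B": random_peaks(rng, 30)}
        result = ca.merge_overlap_union(sets)
        for a, b in zip(result, result[1:]):
            assert (a.interval.chrom, a.interval.start) < (b.interval.chrom, b.interval.start)
            if a.interval.chrom == b.interval.chrom:
                assert a.interval.end < b.interval.start  # gap of >=1 base


class TestOverlapFilter:
    def test_empty_reference_keep(self):
        q = [ca.Peak(ca.GenomicInterval("chr1", 0, 10))]
        assert ca.overlap_filter(q, [], mode="keep") == []
        assert ca.overlap_filter(q, [], mode="drop") == q

    def test_keep_drop_example(self):
        q = [
            ca.Peak(ca.GenomicInterval("chr1", 0, 10)),
            ca.Peak(ca.GenomicInterval("chr1", 20, 30)),
        ]
        ref = [ca.Peak(ca.GenomicInterval("chr1", 9, 15))]
        assert ca.overlap_filter(q, ref, "keep") == [q[0]]
        assert ca.overlap_filter(q, ref, "drop") == [q[1]]

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            ca.overlap_filter([], [], mode="invert")

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_and_pairwise_oracle(self, seed):
        """keep and drop partition the query, and agree with brute-force
        pairwise overlap testing."""
        rng = np.random.default_rng(100 + seed)
        q = random_peaks(rng, 25)
        ref = random_peaks(rng, 25)
        kept = ca.overlap_filter(q, ref, "keep")
        dropped = ca.overlap_filter(q, ref, "drop")
        assert sorted(kept + dropped, key=id) == sorted(q, key=id)
        for p in q:
            expected = any(brute_force_overlaps(p, r) for r in ref)
            assert (p in kept) == expected


GENES = [
    ca.GeneModel("gA", "chr1", "+", 300, (ca.GenomicInterval("chr1", 300, 800),)),
    ca.GeneModel("gB", "chr1", "+", 1600, (ca.GenomicInterval("chr1", 1600, 2000),)),
]


class TestNearestTss:
    def test_exact_hit(self):
        p = ca.Peak(ca.GenomicInterval("chr1", 900, 1100), summit=1000)
        genes = [ca.GeneModel("g", "chr1", "+", 1000)]
        assert ca.nearest_tss(p, genes) == ("g", 0)

    def test_minimum_over_tss_set_and_sign(self):
        p = ca.Peak(ca.GenomicInterval("chr1", 900, 1100), summit=1000)
        gid, dist = ca.nearest_tss(p, GENES)
        assert (gid, dist) == ("gB", -600)  # 1600 closer than 300; upstream of TSS

    def test_minus_strand_sign_convention(self):
        p = ca.Peak(ca.GenomicInterval("chr1", 900, 1100), summit=1000)
        genes = [ca.GeneModel("g", "chr1", "-", 900)]
        # anchor 1000 is upstream of a minus-strand TSS at 900
        assert ca.nearest_tss(p, genes) == ("g", -100)

    def test_missing_chromosome_annotated_not_raised(self):
        p = ca.Peak(ca.GenomicInterval("chr9", 0, 10))
        assert ca.nearest_tss(p, GENES) == (None, None)

    def test_midpoint_used_without_summit(self):
        p = ca.Peak(ca.GenomicInterval("chr1", 1590, 1612))
        gid, dist = ca.nearest_tss(p, GENES)
        assert gid == "gB" and dist == 1601 - 1600

    def test_tie_broken_by_coordinate(self):
        genes = [
            ca.GeneModel("zz", "chr1", "+", 900),
            ca.GeneModel("aa", "chr1", "+", 1100),
        ]
        p = ca.Peak(ca.GenomicInterval("chr1", 950, 1050), summit=1000)
        assert ca.nearest_tss(p, genes)[0] == "zz"

    @given(shift=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_distance_invariant_under_coordinate_shift(self, shift):
        p = ca.Peak(ca.GenomicInterval("chr1", 900, 1100), summit=1000)
        _, d0 = ca.nearest_tss(p, GENES)
        shifted_genes = [
            ca.GeneModel(g.gene_id, g.chrom, g.strand, g.tss + shift,
                         tuple(ca.GenomicInterval(e.chrom, e.start + shift, e.end + shift)
                               for e in g.exons))
            for g in GENES
        ]
        ps = ca.Peak(ca.GenomicInterval("chr1", 900 + shift, 1100 + shift), summit=1000 + shift)
        _, d1 = ca.nearest_tss(ps, shifted_genes)
        assert d0 == d1


class TestClassifyLocation:
    def test_summit_at_tss(self):
        p = ca.Peak(ca.GenomicInterval("chr1", 250, 350), summit=300)
        assert ca.classify_location(p, GENES) == "TSS"

    def test_intragenic_far_from_tss(self):
        genes = [ca.GeneModel("g", "chr1", "+", 0,
                              (ca.GenomicInterval("chr1", 0, 50_000),))]
        p = ca.Peak(ca.GenomicInterval("chr1", 9_900, 10_100), summit=10_000)
        assert ca.classify_location(p, genes) == "intragenic"

    def test_intergenic_on_geneless_chromosome(self):
        p = ca.Peak(ca.GenomicInterval("chr7", 100, 200), summit=150)
        assert ca.classify_location(p, GENES) == "intergenic"

    def test_window_boundary_inclusive(self):
        genes = [ca.GeneModel("g", "chr1", "+", 300,
                              (ca.GenomicInterval("chr1", 300, 900),))]
        p = ca.Peak(ca.GenomicInterval("chr1", 700, 900), summit=800)
        assert ca.classify_location(p, genes, tss_window=500) == "TSS"
        assert ca.classify_location(p, genes, tss_window=499) == "intragenic"


def test_venn_counts_by_signature():
    sets = {
        "A": [ca.Peak(ca.GenomicInterval("chr1", 0, 100)),
              ca.Peak(ca.GenomicInterval("chr1", 500, 600))],
        "B": [ca.Peak(ca.GenomicInterval("chr1", 50, 150))],
    }
    counts = venn_counts(ca.merge_overlap_union(sets))
    assert counts == {"A&B": 1, "A": 1}
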