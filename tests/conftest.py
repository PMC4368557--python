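"""Shared fixtures: a session-scoped default simulation and helpers."""

import numpy as np
import pytest

import chiparch as ca


@pytest.fixture(scope="session")
def sim_ref():
    """Default synthetic reference (seeded): genome, genes, planted truth."""
    return ca.generate_reference(ca.SimConfig(seed=11))


@pytest.fixture(scope="session")
def sim_reads(sim_ref):
    """Reads and library stats for all three conditions."""
    out = {}
    for condition in ("wt", "ko", "control"):
        reads, stats = ca.simulate_reads(sim_ref, condition)
        out[condition] = (reads, stats)
    return out


@pytest.fixture(scope="session")
def filtered_peaks(sim_ref, sim_reads):
    """Candidate peaks carried through count annotation and filtering."""
    wt, st_wt = sim_reads["wt"]
    ctrl, st_ctrl = sim_reads["control"]
    cands = ca.candidate_peaks(sim_ref, n_decoys=50)
    cands = ca.annotate_counts(cands, wt, target="raw")
    cands = ca.annotate_counts(cands, ctrl, target="control")
    return ca.filter_peaks(cands, st_wt, st_ctrl)


def random_peaks(rng, n, chrom="chr1", max_pos=10_000, max_len=400):
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        end = start + int(rng.integers(1, max_len))
        peaks.append(ca.Peak(ca.GenomicInterval(chrom, start, end)))
    return peaks
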