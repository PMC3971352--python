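"""Transition detection: ratio track, filtering, CBS, refinement, walker."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hyp

import strandtools as st
from strandtools.io_binning import CRICK, WATSON
from strandtools.sce_detect import (
    MISORIENTATION_CANDIDATE,
    SCE,
    walker_refine,
)

from conftest import make_counts


# ---------------------------------------------------------------------------
# ratio track

@pytest.mark.parametrize("w,c,raw,level", [
    (100, 0, 1.0, 1),
    (0, 100, -1.0, -1),
    (50, 50, 0.0, 0),
    (75, 25, 0.5, 1),
])
def test_ratio_track_values(w, c, raw, level):
    counts = make_counts({"chr1": ([w, 0], [c, 0])})
    track = st.compute_ratio_track(counts, "chr1")
    assert track.raw[0] == pytest.approx(raw)
    assert track.level[0] == level
    assert np.isnan(track.raw[1]) and track.excluded[1]  # empty bin masked


# ---------------------------------------------------------------------------
# bin filtering

def test_filter_masks_gross_outlier_only():
    counts = make_counts({"chr1": ([5, 5, 5, 5, 50], [5, 5, 5, 5, 50])})
    mask = st.filter_bins(counts, sd_threshold=0.2)["chr1"]
    assert mask[4]
    assert not mask[:4].any()


def test_filter_infinite_threshold_masks_nothing(clean_library):
    reads, _ = clean_library
    counts = st.bin_reads(reads)
    masks = st.filter_bins(counts, sd_threshold=float("inf"))
    assert not any(m.any() for m in masks.values())


def test_filter_masks_collapsed_repeat_bin(small_lengths):
    import pandas as pd
    cfg = st.SimConfig(chrom_lengths=small_lengths, n_libraries=1,
                       mean_reads=30_000, background=0.0, seed=21)
    reads, _ = st.simulate_library(cfg, 0)
    # plant a collapsed-repeat pileup: ~10x depth inside one bin of chr1
    df = reads.reads
    lam = (df["chrom"] == "chr1").sum() * 200_000 / small_lengths["chr1"]
    extra = df.iloc[: int(9 * lam)].copy()
    extra["chrom"] = "chr1"
    extra["start"] = np.linspace(1_000_000, 1_199_900, len(extra)).astype(int)
    piled = st.ReadSet(reads.library_id, pd.concat([df, extra]),
                       reads.chrom_lengths)
    mask = st.filter_bins(st.bin_reads(piled), 0.2)["chr1"]
    assert mask[5]                       # the pileup bin (1.0-1.2 Mb)
    assert mask.sum() <= 2               # and essentially nothing else


def test_filter_keeps_half_depth_chromosome(small_lengths):
    # a monosome deviates from the library mean but not from itself
    cfg = st.SimConfig(chrom_lengths=small_lengths, n_libraries=1,
                       mean_reads=30_000, background=0.0,
                       haploid_chromosomes=("chr3",), seed=2)
    reads, _ = st.simulate_library(cfg, 0)
    counts = st.bin_reads(reads)
    mask = st.filter_bins(counts, 0.2)["chr3"]
    assert mask.mean() < 0.2


# ---------------------------------------------------------------------------
# segmentation

def test_segment_track_exact_level_change():
    counts = make_counts({"chr1": ([50, 50, 50, 25, 25, 25],
                                   [0, 0, 0, 25, 25, 25])})
    track = st.compute_ratio_track(counts, "chr1")
    segments, changepoints = st.segment_track(
        track, rng=np.random.default_rng(0))
    assert [s.level for s in segments] == [1, 0]
    assert changepoints == [(2, 3)]


def test_segment_track_flat_has_no_changepoint():
    counts = make_counts({"chr1": ([25] * 5, [25] * 5)})
    track = st.compute_ratio_track(counts, "chr1")
    segments, changepoints = st.segment_track(
        track, rng=np.random.default_rng(0))
    assert len(segments) == 1 and changepoints == []


def test_segment_track_noisy_contains_planted_changepoint(small_lengths):
    cfg = st.SimConfig(chrom_lengths=small_lengths, n_libraries=1,
                       mean_reads=30_000, background=0.03,
                       sce_positions={0: {"chr1": [2_400_000]}}, seed=33)
    reads, truth = st.simulate_library(cfg, 0)
    counts = st.bin_reads(reads)
    mask = st.filter_bins(counts)["chr1"]
    track = st.compute_ratio_track(counts, "chr1", mask)
    segments, changepoints = st.segment_track(
        track, rng=np.random.default_rng(1))
    assert len(changepoints) == 1
    left_bin, right_bin = changepoints[0]
    lo, hi = left_bin * 200_000, (right_bin + 1) * 200_000
    assert lo <= 2_400_000 <= hi


# ---------------------------------------------------------------------------
# iterative refinement

def _clean_transition_reads(chrom_length, breakpoint, spacing):
    """Deterministic CC -> WC layout: C reads everywhere, W on one homologue
    downstream of the breakpoint."""
    pos_c = np.arange(0, chrom_length, spacing)
    pos_w = np.arange(breakpoint + spacing // 3, chrom_length, 2 * spacing)
    positions = np.concatenate([pos_c, pos_w])
    strands = np.array([CRICK] * len(pos_c) + [WATSON] * len(pos_w))
    return positions, strands


def test_refinement_first_iteration_uses_interval_fifth():
    positions, strands = _clean_transition_reads(10_000_000, 5_000_000, 500)
    interval, trace, refined = st.refine_interval(
        (4_800_000, 5_200_000), positions, strands, 10_000_000,
        rng=np.random.default_rng(0))
    assert refined
    # first accepted interval comes from 80 kb bins: width 160 kb
    assert trace[1][1] - trace[1][0] == 160_000
    assert interval[0] <= 5_000_000 <= interval[1]


def test_refinement_stops_below_min_reads():
    positions = np.arange(0, 400_000, 10_000)  # 40 reads < 50
    strands = np.array([CRICK] * len(positions))
    interval, trace, refined = st.refine_interval(
        (0, 400_000), positions, strands, 10_000_000,
        rng=np.random.default_rng(0))
    assert interval == (0, 400_000) and not refined


def test_refinement_trace_is_nested_and_shrinking():
    positions, strands = _clean_transition_reads(10_000_000, 5_000_000, 400)
    interval, trace, refined = st.refine_interval(
        (4_800_000, 5_200_000), positions, strands, 10_000_000,
        rng=np.random.default_rng(0))
    widths = [b - a for a, b in trace]
    assert all(w2 <= w1 for w1, w2 in zip(widths, widths[1:]))
    for (a1, b1), (a2, b2) in zip(trace, trace[1:]):
        pad = (b1 - a1) // 2
        assert a2 >= a1 - pad and b2 <= b1 + pad


# ---------------------------------------------------------------------------
# walker: literal-rule oracle

def walker_oracle(positions, strands, homo, from_left=True, start_index=0):
    """Exhaustive scan implementing the stated checks literally."""
    order = np.argsort(positions, kind="mergesort")
    pos = positions[order]
    strs = strands[order]
    if not from_left:
        pos, strs = pos[::-1], strs[::-1]
    opp = CRICK if homo == WATSON else WATSON
    for i in range(len(pos)):
        if strs[i] != opp or i == 0 or i < start_index:
            continue
        preceding = strs[max(0, i - 10):i]
        if any(s != homo for s in preceding):
            continue
        window = strs[i:i + 20]
        need = 4 if len(window) >= 20 else max(1, math.ceil(0.2 * len(window)))
        if sum(s == opp for s in window) < need:
            continue
        a, b = int(pos[i - 1]), int(pos[i])
        return (min(a, b), max(a, b)), True
    if len(pos) == 0:
        return (0, 0), False
    return (int(pos.min()), int(pos.max())), False


def test_walker_clean_transition():
    positions = np.arange(50)
    strands = np.array([CRICK] * 30 + [WATSON] * 20)
    interval, ok = walker_refine(positions, strands, CRICK)
    assert ok and interval == (29, 30)


def test_walker_rejects_isolated_spurious_read():
    # one spurious W deep inside the C run (its 20-read window holds < 4
    # W reads) is skipped; the true transition is found afterwards
    strands = np.array([CRICK] * 20 + [WATSON] + [CRICK] * 30
                       + [WATSON] * 20)
    positions = np.arange(len(strands)) * 100
    interval, ok = walker_refine(positions, strands, CRICK)
    assert ok
    assert interval == (5000, 5100)


def test_walker_matches_oracle_on_random_vectors():
    rng = np.random.default_rng(42)
    for trial in range(1000):
        n = int(rng.integers(2, 80))
        strands = np.where(rng.random(n) < rng.uniform(0.05, 0.95),
                           WATSON, CRICK)
        positions = np.sort(rng.integers(0, 100_000, size=n))
        homo = WATSON if rng.random() < 0.5 else CRICK
        from_left = bool(rng.random() < 0.5)
        start = int(rng.integers(0, max(1, n // 2)))
        got = walker_refine(positions, strands, homo, from_left=from_left,
                            start_index=start)
        want = walker_oracle(positions, strands, homo, from_left=from_left,
                             start_index=start)
        assert got == want, f"trial {trial}"


@settings(max_examples=200, deadline=None)
@given(hyp.lists(hyp.sampled_from([WATSON, CRICK]), min_size=2, max_size=60),
       hyp.sampled_from([WATSON, CRICK]), hyp.booleans())
def test_walker_oracle_equivalence_property(strand_list, homo, from_left):
    strands = np.array(strand_list)
    positions = np.arange(len(strands)) * 37
    got = walker_refine(positions, strands, homo, from_left=from_left)
    want = walker_oracle(positions, strands, homo, from_left=from_left)
    assert got == want


# ---------------------------------------------------------------------------
# end-to-end detection

@pytest.fixture(scope="module")
def detection_run():
    lengths = {"chr1": 30_000_000, "chr2": 30_000_000}
    sce_pos = {0: {"chr1": [7_000_000, 21_000_000], "chr2": [11_000_000]}}
    cfg = st.SimConfig(chrom_lengths=lengths, n_libraries=1,
                       mean_reads=120_000, background=0.01,
                       sce_positions=sce_pos, seed=17)
    reads, truth = st.simulate_library(cfg, 0)
    counts = st.bin_reads(reads)
    events = st.detect_events(reads, counts, st.call_ploidy(counts), seed=9)
    return truth, events


def test_detect_events_recovers_planted_sces(detection_run):
    truth, events = detection_run
    assert len(events) == len(truth.sces) == 3
    for chrom, pos, _ in truth.sces:
        matching = [e for e in events if e.chrom == chrom
                    and abs((e.start + e.end) / 2 - pos) < 100_000]
        assert len(matching) == 1
        assert matching[0].kind == SCE


def test_detected_intervals_nest(detection_run):
    _, events = detection_run
    for e in events:
        glo, ghi = e.gross_interval
        pad = (ghi - glo) // 2
        rlo, rhi = e.refined_interval
        assert glo - pad <= rlo < rhi <= ghi + pad
        assert rlo - (rhi - rlo) <= e.start < e.end <= rhi + (rhi - rlo)


def test_misorientation_candidate_classification(small_lengths):
    seg = ("chr1", 2_000_000, 4_000_000)
    cfg = st.SimConfig(chrom_lengths=small_lengths, n_libraries=10,
                       mean_reads=30_000, background=0.0,
                       misoriented_segments=(seg,), seed=23)
    seen = 0
    for i in range(10):
        reads, truth = st.simulate_library(cfg, i)
        if truth.states["chr1"] not in ("WW", "CC"):
            continue
        counts = st.bin_reads(reads)
        events = st.detect_events(reads, counts, None, seed=1)
        on_chr1 = [e for e in events if e.chrom == "chr1"]
        assert len(on_chr1) == 2
        assert all(e.kind == MISORIENTATION_CANDIDATE for e in on_chr1)
        seen += 1
    assert seen >= 2


def test_haploid_switch_classification(small_lengths):
    lengths = dict(small_lengths, chrX=5_000_000)
    cfg = st.SimConfig(chrom_lengths=lengths, n_libraries=1,
                       mean_reads=40_000, background=0.0,
                       haploid_chromosomes=("chrX",),
                       sce_positions={0: {"chrX": [2_500_000]}}, seed=29)
    reads, truth = st.simulate_library(cfg, 0)
    counts = st.bin_reads(reads)
    events = st.detect_events(reads, counts, st.call_ploidy(counts), seed=1)
    on_x = [e for e in events if e.chrom == "chrX"]
    assert len(on_x) == 1
    assert on_x[0].kind == "haploid-switch"
    assert {on_x[0].left_state, on_x[0].right_state} == {"W", "C"}


def test_mirror_symmetry_of_detection(small_lengths):
    cfg = st.SimConfig(chrom_lengths=small_lengths, n_libraries=1,
                       mean_reads=30_000, background=0.02,
                       sce_positions={0: {"chr1": [2_400_000]}}, seed=31)
    reads, _ = st.simulate_library(cfg, 0)
    mirrored = reads.reads.copy()
    mirrored["strand"] = np.where(mirrored["strand"] == WATSON, CRICK, WATSON)
    reads_m = st.ReadSet(reads.library_id, mirrored, reads.chrom_lengths)
    ev = st.detect_events(reads, st.bin_reads(reads), None, seed=2)
    ev_m = st.detect_events(reads_m, st.bin_reads(reads_m), None, seed=2)
    mirror = {"WW": "CC", "CC": "WW", "WC": "WC"}
    assert len(ev) == len(ev_m) > 0
    for a, b in zip(ev, ev_m):
        assert (a.start, a.end) == (b.start, b.end)
        assert mirror[a.left_state] == b.left_state
        assert mirror[a.right_state] == b.right_state
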