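"""Linkage-group clustering, orientation, haploid routing, contig ordering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

import strandtools as st
from strandtools.assembly import (
    LinkageGroup,
    StateMatrix,
    UNINFORMATIVE,
    contig_distance_matrix,
    group_consensus,
    pairwise_concordance,
)


def _matrix(rows):
    return StateMatrix(states=pd.DataFrame(rows).T)


def test_build_matrix_drops_all_wc_rows_and_columns():
    states = pd.DataFrame({
        "L1": {"c1": "WW", "c2": "WC", "c3": "CC"},
        "L2": {"c1": "WC", "c2": "WC", "c3": "WC"},   # failed library
        "L3": {"c1": "CC", "c2": "WC", "c3": "WW"},
    })
    m = st.build_state_matrix(states)
    assert m.excluded_libraries == ["L2"]
    assert m.excluded_contigs == ["c2"]               # degenerate contig
    assert set(m.states.index) == {"c1", "c3"}


def test_build_matrix_keeps_clean_input(clean_config):
    states = pd.DataFrame({
        "L1": {"c1": "WW", "c2": "WC"},
        "L2": {"c1": "WC", "c2": "CC"},
    })
    m = st.build_state_matrix(states)
    assert m.excluded_libraries == [] and m.excluded_contigs == []


def test_concordance_modes():
    a = pd.Series(["WW", "CC", "WC", "WW", UNINFORMATIVE])
    b = pd.Series(["WW", "CC", "WC", "WW", "WW"])
    frac, n = st.concordance(a, b)
    assert (frac, n) == (1.0, 4)
    inverted = b.map({"WW": "CC", "CC": "WW", "WC": "WC"})
    frac, n = st.concordance(a, inverted, mode="homozygous-only")
    assert (frac, n) == (0.0, 3)   # mirrored homozygous calls
    frac_all, n_all = st.concordance(a, inverted)
    assert n_all == 4 and frac_all == pytest.approx(1 / 4)  # WC still matches


def test_expected_concordance_of_independent_contigs_by_enumeration():
    """Under independent 1:2:1 segregation the probability two contigs share
    a state is sum p_i^2 = 3/8; the empirical all-states concordance of
    contigs from different chromosomes converges there."""
    probs = {"WW": 0.25, "WC": 0.5, "CC": 0.25}
    match_p = sum(p * p for p in probs.values())
    assert match_p == pytest.approx(3 / 8)
    cfg = st.SimConfig(chrom_lengths={"chrA": 4_000_000, "chrB": 4_000_000},
                       n_libraries=400, mean_reads=4_000, background=0.0,
                       seed=61)
    a_states, b_states = [], []
    for i in range(cfg.n_libraries):
        states = st.simulate_inheritance(cfg, i)
        a_states.append(states["chrA"])
        b_states.append(states["chrB"])
    frac, n = st.concordance(pd.Series(a_states), pd.Series(b_states))
    assert n == 400
    sigma = np.sqrt(match_p * (1 - match_p) / n)
    assert abs(frac - match_p) < 3 * sigma


def test_clustering_simple_threshold_behaviour():
    rows = {
        "c1": ["WW", "WC", "CC", "WW", "WC"],
        "c2": ["WW", "WC", "CC", "WW", "WC"],    # identical to c1
        "c3": ["WW", "CC", "WW", "CC", "WW"],    # 40% match (2 of 5)
    }
    m = StateMatrix(states=pd.DataFrame(rows, index=[f"L{i}" for i in range(5)]).T)
    groups = st.cluster_linkage_groups(m, similarity_threshold=0.85)
    members = sorted(tuple(sorted(g.contigs)) for g in groups)
    assert members == [("c1", "c2"), ("c3",)]
    # unreachable threshold: every contig alone
    singles = st.cluster_linkage_groups(m, similarity_threshold=1.01)
    assert all(len(g) == 1 for g in singles)


def _simulated_matrix(n_frag, inverted_fraction, sce_rate, n_lib=60, seed=5,
                      haploid=()):
    lengths = {"chrA": 24_000_000, "chrB": 24_000_000}
    if haploid:
        lengths.update({c: 24_000_000 for c in haploid})
    cfg = st.SimConfig(chrom_lengths=lengths, n_libraries=n_lib,
                       mean_reads=2 * len(lengths) * 24_000, background=0.0,
                       sce_rate=sce_rate, haploid_chromosomes=tuple(haploid),
                       seed=seed)
    table, truth = st.fragment_genome(cfg, n_fragments=n_frag,
                                      inverted_fraction=inverted_fraction)
    calls = {}
    for i in range(n_lib):
        reads, _ = st.simulate_library(cfg, i)
        remapped = st.remap_to_fragments(reads, truth)
        counts = st.bin_reads(remapped, 200_000)
        calls[remapped.library_id] = [
            st.call_chromosome_state(counts, c) for c in counts.chromosomes]
    matrix = st.build_state_matrix(st.matrix_from_calls(calls))
    return matrix, truth


@pytest.fixture(scope="module")
def fragmented_run():
    return _simulated_matrix(n_frag=10, inverted_fraction=0.3, sce_rate=0.2)


def test_fragmented_genome_reclusters_into_pure_groups(fragmented_run):
    matrix, truth = fragmented_run
    groups = st.cluster_linkage_groups(matrix)
    merged, heat = st.reorient_and_merge(matrix, groups)
    assert len(merged) == 2
    ti = truth.set_index("contig")
    for g in merged:
        assert len(set(ti.loc[g.contigs, "source_chrom"])) == 1
        # orientation flags match truth up to one global flip per group
        rel = [(g.orientations[c] == "reverse") ^ (o == "reverse")
               for c, o in ti.loc[g.contigs, "orientation"].items()]
        assert len(set(rel)) == 1


def test_reorientation_never_decreases_summed_concordance(fragmented_run):
    """The inversion phase only ever accepts gain, so re-scoring the
    *original* partition with the returned orientation flips cannot fall
    below the starting total."""
    from strandtools.assembly import _INVERT, _summed_concordance
    matrix, _ = fragmented_run
    groups = st.cluster_linkage_groups(matrix)
    before = _summed_concordance(
        {g.group_id: group_consensus(matrix, g) for g in groups})
    merged, _ = st.reorient_and_merge(matrix, groups)
    flipped = {c: o for g in merged for c, o in g.orientations.items()}
    updated = {}
    for g in groups:
        cons = group_consensus(matrix, g)
        # all members of an original group share one polarity decision
        if flipped[g.contigs[0]] == "reverse":
            cons = cons.map(_INVERT)
        updated[g.group_id] = cons
    assert _summed_concordance(updated) >= before - 1e-9


def test_already_consistent_groups_not_inverted():
    # two groups from different chromosomes: inverting either cannot raise
    # their (chance-level) homozygous concordance, so no flip is performed
    rows = {"c1": ["WW", "CC", "WW", "CC", "WW", "WW"],
            "c2": ["WW", "CC", "WW", "CC", "WW", "WW"],
            "c3": ["CC", "CC", "WW", "WW", "CC", "WW"]}
    m = StateMatrix(states=pd.DataFrame(
        rows, index=[f"L{i}" for i in range(6)]).T)
    groups = st.cluster_linkage_groups(m)
    merged, _ = st.reorient_and_merge(m, groups)
    for g in merged:
        assert set(g.orientations.values()) == {"same"}


def test_contig_order_recovered(fragmented_run):
    matrix, truth = fragmented_run
    groups = st.cluster_linkage_groups(matrix)
    merged, _ = st.reorient_and_merge(matrix, groups)
    ti = truth.set_index("contig")
    for g in merged:
        order = st.order_contigs(matrix, g)
        assert sorted(order.order) == sorted(g.contigs)
        if not order.ordered:
            continue
        tau = kendalltau(np.arange(len(order.order)),
                         ti.loc[order.order, "source_start"]).statistic
        assert abs(tau) >= 0.9


def test_order_matches_bruteforce_for_small_groups(fragmented_run):
    matrix, _ = fragmented_run
    groups = st.cluster_linkage_groups(matrix)
    merged, _ = st.reorient_and_merge(matrix, groups)
    for g in merged:
        sub = LinkageGroup(g.group_id, g.contigs[:7],
                           {c: g.orientations[c] for c in g.contigs[:7]})
        dist = contig_distance_matrix(matrix, sub)
        best = min(
            sum(dist.at[a, b] for a, b in zip(perm, perm[1:]))
            for perm in itertools.permutations(dist.index))
        result = st.order_contigs(matrix, sub)
        assert result.path_length == pytest.approx(best, abs=1e-9)


def test_chain_of_three_is_ordered():
    # d(A,B)=0.1, d(B,C)=0.1, d(A,C)=0.2: unique shortest path is A-B-C
    rows = {
        "A": ["WW"] * 8 + ["CC"] * 1 + ["WW"] * 1,
        "B": ["WW"] * 9 + ["WW"] * 1,
        "C": ["WW"] * 8 + ["WW"] * 1 + ["CC"] * 1,
    }
    m = StateMatrix(states=pd.DataFrame(
        rows, index=[f"L{i}" for i in range(10)]).T)
    g = LinkageGroup(0, ["A", "B", "C"], {c: "same" for c in "ABC"})
    dist = contig_distance_matrix(m, g)
    assert dist.at["A", "B"] == pytest.approx(0.1)
    assert dist.at["A", "C"] == pytest.approx(0.2)
    order = st.order_contigs(m, g)
    assert order.order in (["A", "B", "C"], ["C", "B", "A"])


def test_identical_states_flagged_unordered():
    rows = {"c1": ["WW", "CC"], "c2": ["WW", "CC"], "c3": ["WW", "CC"]}
    m = StateMatrix(states=pd.DataFrame(rows, index=["L1", "L2"]).T)
    g = LinkageGroup(0, ["c1", "c2", "c3"], {c: "same" for c in rows})
    order = st.order_contigs(m, g)
    assert not order.ordered


def test_path_never_longer_than_identity_order(fragmented_run):
    matrix, _ = fragmented_run
    groups = st.cluster_linkage_groups(matrix)
    merged, _ = st.reorient_and_merge(matrix, groups)
    for g in merged:
        dist = contig_distance_matrix(matrix, g)
        identity = sum(dist.at[a, b]
                       for a, b in zip(g.contigs, g.contigs[1:]))
        assert st.order_contigs(matrix, g).path_length <= identity + 1e-9


def test_haploid_contigs_routed_separately():
    matrix, truth = _simulated_matrix(n_frag=4, inverted_fraction=0.0,
                                      sce_rate=0.0, n_lib=30, seed=9,
                                      haploid=("chrX",))
    hap, hap_groups, rest = st.separate_haploid(matrix)
    ti = truth.set_index("contig")
    x_contigs = set(truth[truth["source_chrom"] == "chrX"]["contig"])
    assert set(hap) == x_contigs
    assert len(hap_groups) == 1 and hap_groups[0].haploid
    assert set(rest.states.index) == set(matrix.states.index) - x_contigs


def test_diploid_contig_with_spurious_homozygous_call_stays_diploid():
    rows = {"cX": ["WW", "CC", "WW", "CC", "WW", "CC"],
            "cD": ["WW", "WC", "CC", "WW", "WC", "CC"],
            "c2": ["WW", "WC", "CC", "WW", "WC", "CC"]}
    m = StateMatrix(states=pd.DataFrame(
        rows, index=[f"L{i}" for i in range(6)]).T)
    hap, _, rest = st.separate_haploid(m)
    assert hap == ["cX"]
    assert "cD" in rest.states.index


def test_clustering_deterministic(fragmented_run):
    matrix, _ = fragmented_run
    g1 = st.cluster_linkage_groups(matrix)
    g2 = st.cluster_linkage_groups(matrix)
    assert [g.contigs for g in g1] == [g.contigs for g in g2]
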