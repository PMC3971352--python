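"""Linkage-group clustering, orientation, and ordering of early-build contigs.

Contigs on the same chromosome co-inherit template strands in every cell,
while contigs on different chromosomes agree only by chance, so the
contigs x libraries state matrix clusters naturally into linkage groups
(one plus-strand and one minus-strand group per chromosome before
reorientation -- a misassembled-orientation contig reads WW where its
chromosome reads CC).  Homozygous-only concordance exposes those mirrored
pairs (near 0 between opposite orientations of the same chromosome), a
greedy inversion pass harmonizes them, and within each group the fraction
of libraries in which two contigs disagree -- disagreement is created by an
SCE falling between them -- acts as a genetic distance whose shortest
Hamiltonian path recovers the physical contig order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strand_state import StateCall

log = logging.getLogger("strandtools")

DEFAULT_SIMILARITY = 0.85
UNINFORMATIVE = ""

_INVERT = {"WW": "CC", "CC": "WW", "WC": "WC", "W": "C", "C": "W",
           UNINFORMATIVE: UNINFORMATIVE}
_HOMOZYGOUS = {"WW", "CC", "W", "C"}


@dataclass
class StateMatrix:
    """Contigs x libraries template-state matrix ('' = uninformative)."""

    states: pd.DataFrame  # index: contigs, columns: libraries
    excluded_libraries: list[str] = field(default_factory=list)
    excluded_contigs: list[str] = field(default_factory=list)

    def informative_count(self, contig: str) -> int:
        row = self.states.loc[contig]
        return int((row != UNINFORMATIVE).sum())


@dataclass
class LinkageGroup:
    group_id: int
    contigs: list[str]
    orientations: dict[str, str]  # contig -> same | reverse (relative polarity)
    haploid: bool = False

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass
class ContigOrder:
    group_id: int
    order: list[str]
    distances: list[float]
    path_length: float
    ordered: bool  # False when states are identical and order is undetermined


def matrix_from_calls(calls_per_library: dict[str, list[StateCall]],
                      contig_lengths: dict[str, int] | None = None,
                      min_length: int = 10_000) -> pd.DataFrame:
    """Assemble the raw contig x library state table from per-library calls.

    Contigs below ``min_length`` (when lengths are known) are dropped up
    front: very short contigs rarely reach the read minimum and add noise.
    """
    table: dict[str, dict[str, str]] = {}
    for lib, calls in calls_per_library.items():
        for call in calls:
            if contig_lengths is not None and \
                    contig_lengths.get(call.chrom, 0) < min_length:
                continue
            table.setdefault(call.chrom, {})[lib] = (
                call.state if call.informative else UNINFORMATIVE)
    df = pd.DataFrame(table).T.fillna(UNINFORMATIVE)
    return df.sort_index()


def build_state_matrix(states: pd.DataFrame) -> StateMatrix:
    """Drop all-WC libraries and all-WC contigs before clustering.

    A library that is WC on every contig almost certainly failed BrdU
    strand removal; a contig that is WC in every library is probably
    degenerate sequence attracting reads from both strands.
    """
    if states.shape[0] < 2 or states.shape[1] < 2:
        raise ValueError("need at least two contigs and two libraries")

    def all_wc(vec: pd.Series) -> bool:
        informative = vec[vec != UNINFORMATIVE]
        return len(informative) > 0 and (informative == "WC").all()

    bad_libs = [lib for lib in states.columns if all_wc(states[lib])]
    trimmed = states.drop(columns=bad_libs)
    bad_contigs = [ctg for ctg in trimmed.index if all_wc(trimmed.loc[ctg])]
    trimmed = trimmed.drop(index=bad_contigs)
    for lib in bad_libs:
        log.info("library %s excluded: WC on every contig (failed library?)", lib)
    for ctg in bad_contigs:
        log.info("contig %s excluded: WC in every library (degenerate sequence?)",
                 ctg)
    if trimmed.shape[0] == 0 or trimmed.shape[1] == 0:
        raise ValueError("every contig or library was excluded as all-WC")
    return StateMatrix(states=trimmed, excluded_libraries=bad_libs,
                       excluded_contigs=bad_contigs)


def concordance(a: pd.Series, b: pd.Series, mode: str = "all-states"
                ) -> tuple[float, int]:
    """Fraction of mutually informative libraries with identical state.

    ``all-states`` uses every mutually informative library;
    ``homozygous-only`` restricts to libraries where both contigs are
    homozygous, which makes opposite-orientation contigs of one chromosome
    score near 0 (their WW/CC calls are mirrored).  Returns (fraction,
    number of libraries used); the fraction is NaN when that number is 0.
    """
    mask = (a != UNINFORMATIVE) & (b != UNINFORMATIVE)
    if mode == "homozygous-only":
        mask &= a.isin(_HOMOZYGOUS) & b.isin(_HOMOZYGOUS)
    elif mode != "all-states":
        raise ValueError(f"unknown mode {mode!r}")
    n = int(mask.sum())
    if n == 0:
        return float("nan"), 0
    return float((a[mask] == b[mask]).mean()), n


def _majority_state(column: pd.Series) -> str:
    votes = column[column != UNINFORMATIVE]
    if len(votes) == 0:
        return UNINFORMATIVE
    counts = votes.value_counts()
    top = counts[counts == counts.max()]
    if len(top) > 1:
        return UNINFORMATIVE  # tie
    return str(top.index[0])


def group_consensus(matrix: StateMatrix, group: LinkageGroup) -> pd.Series:
    """Per-library majority state over the group's members (orientation-corrected)."""
    rows = []
    for ctg in group.contigs:
        row = matrix.states.loc[ctg]
        if group.orientations.get(ctg, "same") == "reverse":
            row = row.map(_INVERT)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.apply(_majority_state, axis=0)


def cluster_linkage_groups(
    matrix: StateMatrix,
    similarity_threshold: float = DEFAULT_SIMILARITY,
    min_shared: int = 1,
) -> list[LinkageGroup]:
    """Greedy seeded clustering of contigs into linkage groups.

    The two contigs informative in the most libraries seed the first
    group(s); every remaining contig (in descending informative count, ties
    by name) joins the existing group with the highest all-states
    concordance to the group consensus when that concordance reaches the
    threshold, else founds a new group.  Deterministic given the matrix.
    """
    contigs = sorted(
        matrix.states.index,
        key=lambda c: (-matrix.informative_count(c), c),
    )
    groups: list[LinkageGroup] = []
    consensi: list[pd.Series] = []

    def new_group(ctg: str) -> None:
        g = LinkageGroup(group_id=len(groups), contigs=[ctg],
                         orientations={ctg: "same"})
        groups.append(g)
        consensi.append(matrix.states.loc[ctg].copy())

    def try_join(ctg: str) -> bool:
        best_idx, best_frac = -1, -1.0
        row = matrix.states.loc[ctg]
        for idx, cons in enumerate(consensi):
            frac, n = concordance(row, cons, mode="all-states")
            if n >= min_shared and not np.isnan(frac) and frac > best_frac:
                best_idx, best_frac = idx, frac
        if best_idx >= 0 and best_frac >= similarity_threshold:
            g = groups[best_idx]
            g.contigs.append(ctg)
            g.orientations[ctg] = "same"
            consensi[best_idx] = group_consensus(matrix, g)
            return True
        return False

    for ctg in contigs:
        if not groups:
            new_group(ctg)
        elif not try_join(ctg):
            new_group(ctg)
    return groups


def pairwise_concordance(matrix: StateMatrix, groups: list[LinkageGroup],
                         mode: str = "homozygous-only") -> pd.DataFrame:
    cons = {g.group_id: group_consensus(matrix, g) for g in groups}
    ids = [g.group_id for g in groups]
    out = pd.DataFrame(np.nan, index=ids, columns=ids, dtype=float)
    for i, j in itertools.combinations(ids, 2):
        frac, n = concordance(cons[i], cons[j], mode=mode)
        out.at[i, j] = out.at[j, i] = frac
    for i in ids:
        out.at[i, i] = 1.0
    return out


def _summed_concordance(cons: dict[int, pd.Series]) -> float:
    total = 0.0
    for i, j in itertools.combinations(sorted(cons), 2):
        frac, n = concordance(cons[i], cons[j], mode="homozygous-only")
        if n > 0 and not np.isnan(frac):
            total += frac
    return total


def reorient_and_merge(
    matrix: StateMatrix,
    groups: list[LinkageGroup],
    similarity_threshold: float = DEFAULT_SIMILARITY,
    max_iterations: int = 100,
) -> tuple[list[LinkageGroup], pd.DataFrame]:
    """Greedy reorientation of mirrored groups, then merging of matching ones.

    Iteratively inverts the group whose inversion most increases the summed
    pairwise homozygous-only concordance (stopping when no inversion
    helps; a group is never inverted twice in a row), then merges group
    pairs whose all-states consensus concordance reaches the clustering
    threshold.  Returns the merged groups and the final pairwise
    homozygous-only concordance matrix.
    """
    work = [LinkageGroup(g.group_id, list(g.contigs), dict(g.orientations),
                         g.haploid) for g in groups]
    cons = {g.group_id: group_consensus(matrix, g) for g in work}
    total = _summed_concordance(cons)
    last_inverted: int | None = None
    for _ in range(max_iterations):
        best_gain, best_id = 0.0, None
        for g in work:
            if g.group_id == last_inverted:
                continue  # oscillation guard
            trial = dict(cons)
            trial[g.group_id] = cons[g.group_id].map(_INVERT)
            gain = _summed_concordance(trial) - total
            if gain > best_gain + 1e-12:
                best_gain, best_id = gain, g.group_id
        if best_id is None:
            break
        g = next(g for g in work if g.group_id == best_id)
        g.orientations = {c: ("same" if o == "reverse" else "reverse")
                          for c, o in g.orientations.items()}
        cons[best_id] = cons[best_id].map(_INVERT)
        total += best_gain
        last_inverted = best_id
    else:
        log.warning("reorientation hit the iteration cap (%d)", max_iterations)

    # merge groups whose consensus profiles now agree
    parent = {g.group_id: g.group_id for g in work}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations([g.group_id for g in work], 2):
        frac, n = concordance(cons[a], cons[b], mode="all-states")
        if n > 0 and not np.isnan(frac) and frac >= similarity_threshold:
            parent[find(b)] = find(a)

    merged: dict[int, LinkageGroup] = {}
    for g in sorted(work, key=lambda g: g.group_id):
        root = find(g.group_id)
        if root not in merged:
            merged[root] = LinkageGroup(len(merged), [], {}, g.haploid)
        merged[root].contigs.extend(g.contigs)
        merged[root].orientations.update(g.orientations)
    final = list(merged.values())
    heat = pairwise_concordance(matrix, final, mode="homozygous-only")
    return final, heat


def separate_haploid(
    matrix: StateMatrix,
    relative_depth: dict[str, float] | None = None,
    min_informative: int = 5,
    similarity_threshold: float = DEFAULT_SIMILARITY,
) -> tuple[list[str], list[LinkageGroup], StateMatrix]:
    """Route haploid-behaving contigs to their own clustering.

    A contig is haploid-behaving when it is informative in at least
    ``min_informative`` libraries, never heterozygous, and (when depth is
    supplied) sits near half the library depth.  Its WW/CC calls are
    reduced to W/C and clustered separately; the remaining diploid matrix
    is returned alongside.
    """
    haploid_contigs = []
    for ctg in matrix.states.index:
        row = matrix.states.loc[ctg]
        informative = row[row != UNINFORMATIVE]
        if len(informative) < min_informative or (informative == "WC").any():
            continue
        if relative_depth is not None:
            d = relative_depth.get(ctg)
            if d is None or not 0.25 <= d <= 0.75:
                continue
        haploid_contigs.append(ctg)
    if not haploid_contigs:
        return [], [], matrix
    reduced = matrix.states.loc[haploid_contigs].replace(
        {"WW": "W", "CC": "C"})
    groups: list[LinkageGroup] = []
    if len(haploid_contigs) >= 2:
        sub = StateMatrix(states=reduced)
        groups = cluster_linkage_groups(sub, similarity_threshold)
        for g in groups:
            g.haploid = True
    else:
        groups = [LinkageGroup(0, list(haploid_contigs),
                               {haploid_contigs[0]: "same"}, haploid=True)]
    rest = StateMatrix(
        states=matrix.states.drop(index=haploid_contigs),
        excluded_libraries=matrix.excluded_libraries,
        excluded_contigs=matrix.excluded_contigs,
    )
    return haploid_contigs, groups, rest


# ---------------------------------------------------------------------------
# contig ordering (shortest Hamiltonian path on the SCE-distance matrix)

def contig_distance_matrix(matrix: StateMatrix, group: LinkageGroup
                           ) -> pd.DataFrame:
    """Pairwise genetic distance: fraction of mutually informative libraries
    with differing (orientation-corrected) state; undefined pairs get the
    maximum distance 1.0 with a warning."""
    rows = {}
    for ctg in group.contigs:
        row = matrix.states.loc[ctg]
        if group.orientations.get(ctg, "same") == "reverse":
            row = row.map(_INVERT)
        rows[ctg] = row
    names = sorted(group.contigs)
    dist = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        frac, n = concordance(rows[a], rows[b], mode="all-states")
        if n == 0 or np.isnan(frac):
            log.warning("no mutually informative library for %s vs %s; "
                        "distance set to 1.0", a, b)
            d = 1.0
        else:
            d = 1.0 - frac
        dist.at[a, b] = dist.at[b, a] = d
    return dist


def _path_length(order: list[str], dist: pd.DataFrame) -> float:
    return float(sum(dist.at[a, b] for a, b in zip(order, order[1:])))


def _two_opt(order: list[str], dist: pd.DataFrame) -> list[str]:
    improved = True
    best = list(order)
    while improved:
        improved = False
        n = len(best)
        for i in range(n - 1):
            for j in range(i + 1, n):
                trial = best[:i] + best[i:j + 1][::-1] + best[j + 1:]
                if _path_length(trial, dist) < _path_length(best, dist) - 1e-12:
                    best = trial
                    improved = True
    return best


def order_contigs(matrix: StateMatrix, group: LinkageGroup) -> ContigOrder:
    """Order a group's contigs along the shortest Hamiltonian path.

    Best-of-all-starts nearest neighbour seeds a 2-opt refinement
    (deterministic; ties broken by contig name).  Groups whose states are
    identical everywhere are returned in input order, flagged unordered.
    """
    if len(group.contigs) < 2:
        return ContigOrder(group.group_id, list(group.contigs), [], 0.0,
                           ordered=False)
    dist = contig_distance_matrix(matrix, group)
    names = list(dist.index)
    if float(dist.to_numpy().max()) == 0.0:
        return ContigOrder(group.group_id, sorted(group.contigs), [], 0.0,
                           ordered=False)
    # the input order is a candidate too, so the result never loses to it
    best_order = _two_opt(list(group.contigs), dist)
    best_len = _path_length(best_order, dist)
    for start in names:
        order = [start]
        remaining = [n for n in names if n != start]
        while remaining:
            last = order[-1]
            nxt = min(remaining, key=lambda c: (dist.at[last, c], c))
            order.append(nxt)
            remaining.remove(nxt)
        order = _two_opt(order, dist)
        length = _path_length(order, dist)
        if length < best_len - 1e-12:
            best_order, best_len = order, length
    distances = [float(dist.at[a, b]) for a, b in zip(best_order, best_order[1:])]
    return ContigOrder(group.group_id, best_order, distances, best_len,
                       ordered=True)


def groups_to_frame(groups: list[LinkageGroup], matrix: StateMatrix
                    ) -> pd.DataFrame:
    rows = []
    for g in groups:
        for ctg in g.contigs:
            rows.append({
                "contig": ctg,
                "group": g.group_id,
                "orientation": g.orientations.get(ctg, "same"),
                "haploid": g.haploid,
                "informative_libraries": matrix.informative_count(ctg)
                if ctg in matrix.states.index else 0,
            })
    return pd.DataFrame(rows, columns=["contig", "group", "orientation",
                                       "haploid", "informative_libraries"])
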