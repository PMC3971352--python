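"""Placement of orphan scaffolds onto a built genome, and reference rewriting.

An orphan scaffold inherits the template state of the chromosome it really
sits on: a WC scaffold must lie on a WC chromosome in that library, a WW
scaffold on a WW region (same orientation) or a CC region (reverse
orientation), and symmetrically for CC.  Iterating this comparison over a
batch of libraries, and splitting chromosomes at each library's SCE
positions so the comparison is regional, yields a concordance score per
genomic region; the best region localizes the scaffold and the balance of
same- versus reverse-orientation votes orients it.  Gap annotations can
then narrow the placement to candidate assembly gaps, and a small utility
rewrites the reference FASTA (reverse complementing misoriented segments,
inserting placed scaffolds into their primary gaps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_binning import CRICK, WATSON, BinnedCounts
from .rearrange import MisorientationCall
from .sce_detect import SceEvent
from .strand_state import DEFAULT_MIN_READS, StateCall, ratio_level

log = logging.getLogger("strandtools")

#: confidence thresholds: more than 10 informative libraries, more than 60%
#: concordance
DEFAULT_MIN_LIBRARIES = 10
DEFAULT_MIN_CONCORDANCE = 60.0

SAME = "same"
REVERSE = "reverse"
MISMATCH = "mismatch"

_MIRROR = {"WW": "CC", "CC": "WW", WATSON: CRICK, CRICK: WATSON}


@dataclass
class RegionStates:
    """Template states of SCE-delimited chromosome regions, per library.

    ``regions[chrom]`` tiles the chromosome on the common breakpoint grid
    (union of all libraries' transition midpoints); ``states[chrom]`` is a
    regions x libraries DataFrame of state strings ('' = uninformative).
    """

    regions: dict[str, list[tuple[int, int]]]
    states: dict[str, pd.DataFrame]
    haploid: set[str] = field(default_factory=set)

    def libraries(self) -> list[str]:
        for df in self.states.values():
            return list(df.columns)
        return []


def build_region_states(
    counts_per_lib: dict[str, BinnedCounts],
    events_per_lib: dict[str, list[SceEvent]],
    chromosomes: list[str] | None = None,
    haploid: set[str] | None = None,
    min_reads: int = DEFAULT_MIN_READS,
) -> RegionStates:
    """Split chromosomes at SCE positions and call a state per region per library.

    Breakpoints from all libraries are pooled into one grid (the finest
    partition on which every library's state is constant), and each region's
    state is called from the W/C counts of the bins it covers.
    """
    haploid = haploid or set()
    any_counts = next(iter(counts_per_lib.values()))
    if chromosomes is None:
        chromosomes = list(any_counts.chrom_lengths)
    regions: dict[str, list[tuple[int, int]]] = {}
    states: dict[str, pd.DataFrame] = {}
    for chrom in chromosomes:
        length = any_counts.chrom_lengths[chrom]
        cuts = sorted({(e.start + e.end) // 2
                       for evs in events_per_lib.values()
                       for e in evs if e.chrom == chrom})
        bounds = [0] + [c for c in cuts if 0 < c < length] + [length]
        ivs = list(zip(bounds[:-1], bounds[1:]))
        regions[chrom] = ivs
        table = {}
        for lib, counts in counts_per_lib.items():
            bin_size = counts.bin_size
            w = counts.watson[chrom]
            c = counts.crick[chrom]
            starts = np.arange(len(w)) * bin_size
            col = []
            for lo, hi in ivs:
                sel = (starts >= lo) & (starts < hi)
                ww, cc = int(w[sel].sum()), int(c[sel].sum())
                col.append(_call_state(ww, cc, chrom in haploid, min_reads))
            table[lib] = col
        states[chrom] = pd.DataFrame(table, index=range(len(ivs)))
    return RegionStates(regions=regions, states=states, haploid=set(haploid))


def _call_state(w: int, c: int, haploid: bool, min_reads: int) -> str:
    total = w + c
    if total < max(1, min_reads):
        return ""
    if haploid:
        if w == c:
            return ""
        return WATSON if w > c else CRICK
    return {1: "WW", 0: "WC", -1: "CC"}[ratio_level((w - c) / total)]


def call_scaffold_states(
    counts_per_lib: dict[str, BinnedCounts],
    scaffold: str,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[dict[str, StateCall], bool]:
    """Per-library template state of one scaffold, plus a haploid-candidate flag.

    A scaffold that is informative in at least five libraries and never
    heterozygous behaves like a haploid (sex-chromosome) fragment: a diploid
    scaffold is WC in about half of all cells, so an all-homozygous profile
    over >= 5 libraries has < 5% probability.
    """
    calls: dict[str, StateCall] = {}
    for lib, counts in counts_per_lib.items():
        w = int(counts.watson[scaffold].sum())
        c = int(counts.crick[scaffold].sum())
        state = _call_state(w, c, haploid=False, min_reads=min_reads)
        calls[lib] = StateCall(scaffold, state or "unknown", w, c,
                               informative=bool(state))
    informative = [s for s in calls.values() if s.informative]
    haploid_candidate = (
        len(informative) >= 5 and all(s.state != "WC" for s in informative)
    )
    return calls, haploid_candidate


@dataclass
class ScaffoldPlacement:
    scaffold: str
    size: int
    chrom: str | None
    start: int | None
    end: int | None
    orientation: str | None      # same | reverse; None unless confident
    concordance: float
    n_informative: int
    confident: bool
    ambiguous: bool = False
    co_best: list[tuple[str, int, int]] = field(default_factory=list)
    haploid_candidate: bool = False
    primary_gap: tuple[int, int] | None = None
    alternate_gaps: list[tuple[int, int]] = field(default_factory=list)
    n_unbridged: int = 0
    n_bridged: int = 0


NEUTRAL = "neutral"


def _compare(scaffold_state: str, region_state: str) -> str:
    """Vote of one library for one region.

    Heterozygous matches confirm co-location but carry no orientation
    information (WC reads both ways), so they count for concordance only.
    """
    if scaffold_state == "WC":
        return NEUTRAL if region_state == "WC" else MISMATCH
    # homozygous scaffold (incl. haploid W/C regions)
    if region_state in ("WW", WATSON):
        ref = "WW"
    elif region_state in ("CC", CRICK):
        ref = "CC"
    else:
        return MISMATCH
    scaff = {"WW": "WW", "CC": "CC", WATSON: "WW", CRICK: "CC"}.get(scaffold_state)
    if scaff is None:
        return MISMATCH
    return SAME if scaff == ref else REVERSE


def map_scaffold(
    scaffold: str,
    scaffold_size: int,
    scaffold_states: dict[str, StateCall],
    region_states: RegionStates,
    haploid_candidate: bool = False,
    min_libraries: int = DEFAULT_MIN_LIBRARIES,
    min_concordance: float = DEFAULT_MIN_CONCORDANCE,
) -> ScaffoldPlacement:
    """Score every genomic region against the scaffold's state profile.

    Concordance of a region = 100 x (libraries whose scaffold state matches
    the region state, in either orientation) / (libraries informative for
    both).  The best region places the scaffold; ties between disjoint
    regions are reported ambiguous.  Haploid-behaving scaffolds are scored
    only against haploid chromosomes.
    """
    informative_libs = {lib for lib, s in scaffold_states.items() if s.informative}
    if not informative_libs:
        log.warning("scaffold %s: no informative library; placement skipped",
                    scaffold)
        return ScaffoldPlacement(scaffold, scaffold_size, None, None, None, None,
                                 0.0, 0, False, haploid_candidate=haploid_candidate)
    best: list[tuple[str, int, int, float, int, int, int]] = []
    best_conc = -1.0
    for chrom, ivs in region_states.regions.items():
        if haploid_candidate and chrom not in region_states.haploid:
            continue
        table = region_states.states[chrom]
        for ridx, (lo, hi) in enumerate(ivs):
            same = reverse = neutral = n_inf = 0
            for lib in informative_libs:
                if lib not in table.columns:
                    continue
                g = table.at[ridx, lib]
                if not g:
                    continue
                n_inf += 1
                vote = _compare(scaffold_states[lib].state, g)
                if vote == SAME:
                    same += 1
                elif vote == REVERSE:
                    reverse += 1
                elif vote == NEUTRAL:
                    neutral += 1
            if n_inf == 0:
                continue
            conc = 100.0 * (same + reverse + neutral) / n_inf
            entry = (chrom, lo, hi, conc, n_inf, same, reverse)
            if conc > best_conc + 1e-9:
                best, best_conc = [entry], conc
            elif abs(conc - best_conc) <= 1e-9:
                best.append(entry)
    if not best:
        return ScaffoldPlacement(scaffold, scaffold_size, None, None, None, None,
                                 0.0, 0, False, haploid_candidate=haploid_candidate)
    chrom, lo, hi, conc, n_inf, same, reverse = best[0]
    ambiguous = len(best) > 1
    confident = (not ambiguous and n_inf > min_libraries
                 and conc > min_concordance)
    orientation = None
    if confident and same + reverse > 0:
        orientation = SAME if same >= reverse else REVERSE
    return ScaffoldPlacement(
        scaffold=scaffold, size=scaffold_size, chrom=chrom, start=lo, end=hi,
        orientation=orientation, concordance=conc, n_informative=n_inf,
        confident=confident, ambiguous=ambiguous,
        co_best=[(b[0], b[1], b[2]) for b in best],
        haploid_candidate=haploid_candidate,
    )


def crossref_gaps(
    placement: ScaffoldPlacement,
    gaps: pd.DataFrame | None,
    scaffold_size: int | None = None,
) -> ScaffoldPlacement:
    """Cross-reference a placement against assembly gaps in its best region.

    ``gaps`` needs columns chrom, start, end, bridged (bool).  A gap
    qualifies when it is unbridged (unknown size) or bridged with length at
    least the scaffold's; qualifying gaps are ranked unbridged-first by
    size, the top one becoming the primary candidate.  Without a gap table
    the placement is returned unchanged.
    """
    if gaps is None or placement.chrom is None:
        return placement
    size = scaffold_size if scaffold_size is not None else placement.size
    sel = gaps[(gaps["chrom"] == placement.chrom)
               & (gaps["start"] < placement.end)
               & (gaps["end"] > placement.start)]
    bridged_flags = sel["bridged"].astype(bool)
    placement.n_unbridged = int((~bridged_flags).sum())
    placement.n_bridged = int(bridged_flags.sum())
    qualifying = sel[(~bridged_flags) | ((sel["end"] - sel["start"]) >= size)]
    if len(qualifying) == 0:
        return placement
    q = qualifying.copy()
    q["length"] = q["end"] - q["start"]
    q = q.sort_values(["bridged", "length"], ascending=[True, False],
                      kind="mergesort")
    ivs = [(int(r.start), int(r.end)) for r in q.itertuples(index=False)]
    placement.primary_gap = ivs[0]
    placement.alternate_gaps = ivs[1:]
    return placement


def placements_to_frame(placements: list[ScaffoldPlacement]) -> pd.DataFrame:
    rows = []
    for p in placements:
        rows.append({
            "scaffold": p.scaffold,
            "size_kb": p.size / 1000.0,
            "localizes_to": (f"{p.chrom}:{p.start}-{p.end}" if p.chrom else ""),
            "strand": {"same": "+", "reverse": "-", None: ""}[p.orientation],
            "concordance": round(p.concordance, 1),
            "n_libraries": p.n_informative,
            "confident": p.confident,
            "ambiguous": p.ambiguous,
            "gaps_unbridged": p.n_unbridged,
            "gaps_bridged": p.n_bridged,
            "primary_gap": (f"{p.chrom}:{p.primary_gap[0]}-{p.primary_gap[1]}"
                            if p.primary_gap else ""),
            "alternate_gaps": ";".join(
                f"{p.chrom}:{a}-{b}" for a, b in p.alternate_gaps),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference rewriting

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def update_reference(
    sequences: dict[str, str],
    misorientations: list[MisorientationCall] | list[tuple[str, int, int]] = (),
    placements: list[ScaffoldPlacement] = (),
    scaffold_sequences: dict[str, str] | None = None,
    version_suffix: str = "_v2",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Rewrite reference sequences from misorientation and placement calls.

    Misoriented intervals are reverse complemented in place; each confident
    placement with a primary gap has its scaffold (reverse complemented
    first when placed in reverse orientation) written into the central
    portion of the gap, preserving the flanking Ns when the gap is larger.
    A scaffold longer than an unbridged gap (whose true size is unknown)
    replaces the gap entirely, with a ledger note.  Edited records are
    renamed with ``version_suffix``; the edit ledger is returned as a
    DataFrame.  Overlapping edits raise an error listing the conflicts.
    """
    flips: list[tuple[str, int, int]] = []
    for m in misorientations:
        if isinstance(m, MisorientationCall):
            flips.append((m.chrom, m.start, m.end))
        else:
            flips.append((m[0], int(m[1]), int(m[2])))
    inserts = [p for p in placements if p.primary_gap is not None]

    edits_by_chrom: dict[str, list[tuple[int, int, str, object]]] = {}
    for chrom, lo, hi in flips:
        edits_by_chrom.setdefault(chrom, []).append((lo, hi, "flip", None))
    for p in inserts:
        lo, hi = p.primary_gap
        edits_by_chrom.setdefault(p.chrom, []).append((lo, hi, "insert", p))

    conflicts = []
    for chrom, edits in edits_by_chrom.items():
        edits.sort()
        for (s1, e1, k1, _), (s2, e2, k2, _) in zip(edits, edits[1:]):
            if s2 < e1:
                conflicts.append(f"{chrom}:{s1}-{e1} ({k1}) vs {chrom}:{s2}-{e2} ({k2})")
    if conflicts:
        raise ValueError("overlapping reference edits: " + "; ".join(conflicts))

    out = dict(sequences)
    ledger_rows = []
    for chrom, edits in edits_by_chrom.items():
        if chrom not in out:
            raise KeyError(f"no sequence for {chrom}")
        seq = out[chrom]
        for lo, hi, kind, payload in sorted(edits, reverse=True):
            if kind == "flip":
                seq = seq[:lo] + _revcomp(seq[lo:hi]) + seq[hi:]
                ledger_rows.append({"record": chrom, "action": "reverse-complement",
                                    "start": lo, "end": hi, "detail": ""})
            else:
                p = payload
                if scaffold_sequences is None or p.scaffold not in scaffold_sequences:
                    raise KeyError(f"no sequence for scaffold {p.scaffold}")
                frag = scaffold_sequences[p.scaffold]
                if p.orientation == REVERSE:
                    frag = _revcomp(frag)
                gap_len = hi - lo
                note = f"scaffold {p.scaffold} ({p.orientation})"
                if len(frag) <= gap_len:
                    left = (gap_len - len(frag)) // 2
                    seq = (seq[: lo + left] + frag
                           + seq[lo + left + len(frag):])
                else:
                    seq = seq[:lo] + frag + seq[hi:]
                    note += "; scaffold longer than gap, gap replaced entirely"
                ledger_rows.append({"record": chrom, "action": "insert-scaffold",
                                    "start": lo, "end": hi, "detail": note})
        out[chrom] = seq
    renamed = {}
    for name, seq in out.items():
        if name in edits_by_chrom:
            renamed[name + version_suffix] = seq
        else:
            renamed[name] = seq
    ledger = pd.DataFrame(ledger_rows,
                          columns=["record", "action", "start", "end", "detail"])
    return renamed, ledger
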