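"""Strand-seq library simulator with a known-truth ledger.

The generator emulates what a Strand-seq experiment measures: each diploid
chromosome of a daughter cell inherits two parental template strands
(WW : WC : CC at 1 : 2 : 1 under random chromatid segregation), haploid
(sex) chromosomes inherit a single W or C template, and sequencing the
template strands yields directional reads.  On top of that clean signal the
simulator plants, per configuration: sister chromatid exchanges (a template
flip on one homologue downstream of a position), misoriented reference
segments (strand labels inverted inside the segment in *every* library),
regional copy-number changes, orphan-scaffold extractions (reads of a source
interval re-mapped onto a new contig, optionally in reverse orientation),
and a uniform background rate of strand-flipped reads.

Read placement is uniform (no coverage waviness) and reads are fixed-length
point intervals; see docs/methods.md for what this does and does not
emulate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_binning import CRICK, READ_LENGTH, WATSON, ReadSet

log = logging.getLogger("strandtools")

DIPLOID_STATES = ("WW", "WC", "CC")
#: random chromatid segregation gives 1:2:1
SEGREGATION_PROBS = (0.25, 0.5, 0.25)


@dataclass
class SimConfig:
    """Study conditions for a simulated Strand-seq experiment.

    ``sce_positions`` plants explicit breakpoints:
    ``{library_index: {chrom: [pos, ...]}}``; alternatively ``sce_rate``
    draws a Poisson number of breakpoints per chromosome per library.
    ``misoriented_segments`` are (chrom, start, end) reference segments whose
    reads are strand-inverted in every library.  ``scaffold_extractions`` are
    (chrom, start, end, name, orientation) with orientation ``"same"`` or
    ``"reverse"``; reads of the interval are re-mapped onto contig ``name``.
    ``cnv_regions`` are (chrom, start, end, copy_number) depth overrides.
    """

    chrom_lengths: dict[str, int]
    n_libraries: int = 62
    mean_reads: int = 50_000
    background: float = 0.03
    sce_positions: dict[int, dict[str, list[int]]] | None = None
    sce_rate: float = 0.0
    haploid_chromosomes: tuple[str, ...] = ()
    misoriented_segments: tuple[tuple[str, int, int], ...] = ()
    scaffold_extractions: tuple[tuple[str, int, int, str, str], ...] = ()
    ploidy: dict[str, int] = field(default_factory=dict)
    cnv_regions: tuple[tuple[str, int, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background <= 1.0:
            raise ValueError("background rate must be in [0, 1]")
        for chrom, length in self.chrom_lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        if self.sce_positions:
            for lib, per_chrom in self.sce_positions.items():
                for chrom, positions in per_chrom.items():
                    length = self.chrom_lengths[chrom]
                    for p in positions:
                        if not 0 < p < length:
                            raise ValueError(
                                f"SCE position {chrom}:{p} not strictly inside "
                                f"the chromosome (length {length})"
                            )
        intervals = [seg[:3] for seg in self.misoriented_segments]
        intervals += [ext[:3] for ext in self.scaffold_extractions]
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if not 0 <= start < end <= self.chrom_lengths[chrom]:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping planted segments on {chrom}: "
                        f"({s1},{e1}) and ({s2},{e2})"
                    )
        total = sum(self.chrom_lengths.values())
        for chrom, length in self.chrom_lengths.items():
            if self.mean_reads * length / total < 1:
                raise ValueError(
                    f"mean reads per chromosome < 1 for {chrom}; "
                    "increase mean_reads or drop the chromosome"
                )

    def copy_number(self, chrom: str) -> int:
        if chrom in self.ploidy:
            return self.ploidy[chrom]
        return 1 if chrom in self.haploid_chromosomes else 2


@dataclass
class SimTruth:
    """Ground-truth ledger for one simulated library."""

    library_id: str
    states: dict[str, str]
    sces: list[tuple[str, int, int]]  # (chrom, position, homologue index)
    misoriented: tuple[tuple[str, int, int], ...]
    extractions: tuple[tuple[str, int, int, str, str], ...]
    copy_number: dict[str, int]


def _state_rng(config: SimConfig, library_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 1, library_index])


def _read_rng(config: SimConfig, library_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, 2, library_index])


def simulate_inheritance(config: SimConfig, library_index: int) -> dict[str, str]:
    """Draw per-chromosome template states for one library.

    Diploid chromosomes are WW/WC/CC with probability 1/4, 1/2, 1/4;
    haploid chromosomes (copy number 1) are W or C with probability 1/2.
    """
    rng = _state_rng(config, library_index)
    states: dict[str, str] = {}
    for chrom in config.chrom_lengths:
        if config.copy_number(chrom) == 1:
            states[chrom] = WATSON if rng.random() < 0.5 else CRICK
        else:
            states[chrom] = str(rng.choice(DIPLOID_STATES, p=SEGREGATION_PROBS))
    return states


def _plan_sces(config: SimConfig, library_index: int,
               rng: np.random.Generator) -> dict[str, list[int]]:
    if config.sce_positions is not None:
        return {c: sorted(p) for c, p in
                config.sce_positions.get(library_index, {}).items()}
    planned: dict[str, list[int]] = {}
    if config.sce_rate > 0:
        for chrom, length in config.chrom_lengths.items():
            k = rng.poisson(config.sce_rate)
            if k:
                planned[chrom] = sorted(
                    int(p) for p in rng.integers(1, length, size=k)
                )
    return planned


def simulate_library(config: SimConfig, library_index: int) -> tuple[ReadSet, SimTruth]:
    """Simulate the reads of one library together with its truth ledger."""
    rng = _read_rng(config, library_index)
    states = simulate_inheritance(config, library_index)
    sce_plan = _plan_sces(config, library_index, rng)

    total_weight = sum(
        length * config.copy_number(chrom) / 2.0
        for chrom, length in config.chrom_lengths.items()
    )
    chroms_out, starts_out, strands_out = [], [], []
    sces_truth: list[tuple[str, int, int]] = []

    for chrom, length in config.chrom_lengths.items():
        n_copies = config.copy_number(chrom)
        lam = config.mean_reads * (length * n_copies / 2.0) / total_weight
        n_reads = int(rng.poisson(lam))
        pos = rng.integers(0, max(1, length - READ_LENGTH), size=n_reads)
        pos.sort()

        # template per homologue
        state = states[chrom]
        if n_copies == 1:
            templates = np.array([state])
            homolog = np.zeros(n_reads, dtype=np.int64)
        else:
            templates = np.array(list(state))  # e.g. "WC" -> ["W","C"]
            homolog = rng.integers(0, 2, size=n_reads)
        strand = templates[homolog].copy()

        # plant SCEs: template flips downstream of the breakpoint on one homologue
        for p in sce_plan.get(chrom, ()):
            h = int(rng.integers(0, len(templates)))
            sces_truth.append((chrom, int(p), h))
            flip = (homolog == h) & (pos >= p)
            strand[flip] = np.where(strand[flip] == WATSON, CRICK, WATSON)

        # regional copy-number overrides (duplicate or thin reads in place)
        for c, s, e, copy in config.cnv_regions:
            if c != chrom:
                continue
            mult = copy / n_copies
            inside = (pos >= s) & (pos < e)
            if mult < 1.0:
                drop = inside & (rng.random(n_reads) > mult)
                keep = ~drop
                pos, strand, homolog = pos[keep], strand[keep], homolog[keep]
                n_reads = len(pos)
                inside = (pos >= s) & (pos < e)
            elif mult > 1.0:
                extra = int(rng.poisson((mult - 1.0) * lam * (e - s) / length))
                xpos = rng.integers(s, max(s + 1, e - READ_LENGTH), size=extra)
                xhom = (rng.integers(0, len(templates), size=extra)
                        if len(templates) > 1 else np.zeros(extra, dtype=np.int64))
                # extra reads carry the pre-SCE template; regional CNVs and
                # SCEs are not planted on top of each other in one region
                xstr = templates[xhom].copy()
                pos = np.concatenate([pos, xpos])
                strand = np.concatenate([strand, xstr])
                n_reads = len(pos)

        # misoriented reference segments invert the observed strand label
        for c, s, e in config.misoriented_segments:
            if c != chrom:
                continue
            inside = (pos >= s) & (pos < e)
            strand[inside] = np.where(strand[inside] == WATSON, CRICK, WATSON)

        # spurious background: a fraction of reads on the wrong strand
        if config.background > 0 and n_reads:
            flip = rng.random(n_reads) < config.background
            strand[flip] = np.where(strand[flip] == WATSON, CRICK, WATSON)

        chroms_out.append(np.full(n_reads, chrom, dtype=object))
        starts_out.append(pos.astype(np.int64))
        strands_out.append(strand)

    chrom_arr = np.concatenate(chroms_out) if chroms_out else np.array([], dtype=object)
    start_arr = np.concatenate(starts_out) if starts_out else np.array([], dtype=np.int64)
    strand_arr = np.concatenate(strands_out) if strands_out else np.array([], dtype=object)

    chrom_lengths = dict(config.chrom_lengths)

    # orphan-scaffold extractions: re-map reads of the interval onto a contig
    for c, s, e, name, orientation in config.scaffold_extractions:
        inside = (chrom_arr == c) & (start_arr >= s) & (start_arr < e)
        if orientation == "reverse":
            new_start = (e - s) - (start_arr[inside] - s) - READ_LENGTH
            new_start = np.clip(new_start, 0, None)
            flip = strand_arr[inside]
            strand_arr[inside] = np.where(flip == WATSON, CRICK, WATSON)
        else:
            new_start = start_arr[inside] - s
        start_arr[inside] = new_start
        chrom_arr[inside] = name
        chrom_lengths[name] = e - s

    library_id = f"lib{library_index:03d}"
    reads = pd.DataFrame(
        {
            "chrom": pd.Series(chrom_arr, dtype=str),
            "start": start_arr,
            "strand": pd.Series(strand_arr, dtype=str),
            "mapq": np.full(len(start_arr), 60, dtype=int),
            "duplicate": np.zeros(len(start_arr), dtype=bool),
        }
    )
    readset = ReadSet(library_id=library_id, reads=reads, chrom_lengths=chrom_lengths)
    truth = SimTruth(
        library_id=library_id,
        states=states,
        sces=sces_truth,
        misoriented=tuple(config.misoriented_segments),
        extractions=tuple(config.scaffold_extractions),
        copy_number={c: config.copy_number(c) for c in config.chrom_lengths},
    )
    return readset, truth


def simulate_experiment(config: SimConfig) -> tuple[list[ReadSet], list[SimTruth]]:
    """Simulate all libraries of the configured experiment."""
    pairs = [simulate_library(config, i) for i in range(config.n_libraries)]
    return [p[0] for p in pairs], [p[1] for p in pairs]


def fragment_genome(
    config: SimConfig,
    n_fragments: dict[str, int] | int = 3,
    inverted_fraction: float = 0.0,
    boundaries: dict[str, list[int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the configured genome into named contigs with a truth table.

    Fragments tile each chromosome without overlap; contig names are assigned
    in a shuffled order so they carry no information about the source
    chromosome.  A fraction of contigs can be recorded (and later served) in
    inverted orientation.  Returns ``(contig_table, truth_table)`` where the
    contig table is the public (name, length) reference and the truth table
    maps contig -> (source chromosome, offset, orientation).
    """
    rng = np.random.default_rng([config.seed, 3])
    frags: list[tuple[str, int, int]] = []
    for chrom, length in config.chrom_lengths.items():
        if boundaries is not None:
            cuts = [0] + sorted(boundaries.get(chrom, [])) + [length]
        else:
            k = n_fragments[chrom] if isinstance(n_fragments, dict) else n_fragments
            cuts = [round(length * i / k) for i in range(k + 1)]
        for s, e in zip(cuts[:-1], cuts[1:]):
            if e <= s:
                raise ValueError(f"empty or overlapping fragment on {chrom}")
            frags.append((chrom, s, e))

    order = rng.permutation(len(frags))
    names = [f"ctg{int(i):05d}" for i in order]
    flipped = rng.random(len(frags)) < inverted_fraction
    truth = pd.DataFrame(
        {
            "contig": names,
            "source_chrom": [f[0] for f in frags],
            "source_start": [f[1] for f in frags],
            "source_end": [f[2] for f in frags],
            "orientation": np.where(flipped, "reverse", "same"),
        }
    )
    truth["length"] = truth["source_end"] - truth["source_start"]
    table = truth[["contig", "length"]].copy()
    return table, truth


def remap_to_fragments(reads: ReadSet, truth: pd.DataFrame) -> ReadSet:
    """Re-express a library's reads in the coordinates of a fragmented reference.

    Equivalent to aligning the same molecules against the contig build:
    positions become contig-relative and reads on inverted contigs have their
    strand label flipped.
    """
    df = reads.reads
    chrom = df["chrom"].to_numpy(dtype=object)
    start = df["start"].to_numpy().copy()
    strand = df["strand"].to_numpy(dtype=object)
    new_chrom = np.array(chrom, dtype=object)
    keep = np.zeros(len(df), dtype=bool)
    for row in truth.itertuples(index=False):
        inside = (chrom == row.source_chrom) & (start >= row.source_start) \
            & (start < row.source_end)
        keep |= inside
        if row.orientation == "reverse":
            new_pos = (row.source_end - row.source_start) \
                - (start[inside] - row.source_start) - READ_LENGTH
            start[inside] = np.clip(new_pos, 0, None)
            strand[inside] = np.where(strand[inside] == WATSON, CRICK, WATSON)
        else:
            start[inside] = start[inside] - row.source_start
        new_chrom[inside] = row.contig
    out = pd.DataFrame(
        {
            "chrom": pd.Series(new_chrom[keep], dtype=str),
            "start": start[keep].astype(np.int64),
            "strand": pd.Series(strand[keep], dtype=str),
            "mapq": df["mapq"].to_numpy()[keep],
            "duplicate": df["duplicate"].to_numpy()[keep],
        }
    )
    lengths = dict(zip(truth["contig"], truth["length"].astype(int)))
    return ReadSet(library_id=reads.library_id, reads=out, chrom_lengths=lengths)


def write_truth_csv(truths: list[SimTruth], path) -> None:
    rows = []
    for t in truths:
        for chrom, state in t.states.items():
            rows.append({"library": t.library_id, "chrom": chrom,
                         "state": state, "copy_number": t.copy_number[chrom]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_sce_truth_csv(truths: list[SimTruth], path) -> None:
    rows = [
        {"library": t.library_id, "chrom": c, "position": p, "homologue": h}
        for t in truths for (c, p, h) in t.sces
    ]
    pd.DataFrame(rows, columns=["library", "chrom", "position", "homologue"]
                 ).to_csv(path, index=False)
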