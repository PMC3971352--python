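"""Cross-library integration of events: recurrence, misorientations, CNVs.

SCEs are stochastic per cell, so an interval flagged in several libraries is
either a recurrent-SCE region or a genomic rearrangement (translocation,
inversion, deletion) -- both are reported as recurrent events with their
occurrence counts and left to the user to interpret.  A reference-assembly
misorientation, by contrast, flips the observed strand in *every* library,
so WW<->CC candidate events are merged across libraries and scored by
concordance over the informative libraries.  On haploid chromosomes a
misoriented segment is delimited by a *pair* of switch boundaries recurring
in all informative libraries, which distinguishes it from a genuine SCE.
Duplications and deletions are found by segmenting the total-depth track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_binning import BinnedCounts
from .sce_detect import (
    HAPLOID_SWITCH,
    MISORIENTATION_CANDIDATE,
    SceEvent,
    cbs_segment,
)
from .strand_state import round_half_away

log = logging.getLogger("strandtools")


@dataclass
class RecurrentEvent:
    chrom: str
    start: int
    end: int
    count: int
    libraries: list[str]
    fraction_informative: float  # count / number of informative libraries


@dataclass
class MisorientationCall:
    chrom: str
    start: int
    end: int
    concordance: float  # percent of informative libraries showing the flip
    n_libraries: int    # contributing libraries
    note: str = ""


@dataclass
class CnvSegment:
    chrom: str
    start: int
    end: int
    relative_depth: float
    copy_number: int


def _cluster_by_overlap(events: list[SceEvent]) -> list[list[SceEvent]]:
    """Single-linkage clusters of events overlapping by >= 1 bp (per chromosome)."""
    clusters: list[list[SceEvent]] = []
    by_chrom: dict[str, list[SceEvent]] = {}
    for e in events:
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom in sorted(by_chrom):
        evs = sorted(by_chrom[chrom], key=lambda e: (e.start, e.end, e.library_id))
        current: list[SceEvent] = []
        reach = -1
        for e in evs:
            if current and e.start < reach:
                current.append(e)
                reach = max(reach, e.end)
            else:
                if current:
                    clusters.append(current)
                current = [e]
                reach = e.end
        if current:
            clusters.append(current)
    return clusters


def _intersection(cluster: list[SceEvent]) -> tuple[int, int]:
    lo = max(e.start for e in cluster)
    hi = min(e.end for e in cluster)
    if lo >= hi:  # chained overlaps with empty global intersection: report hull
        lo = min(e.start for e in cluster)
        hi = max(e.end for e in cluster)
    return lo, hi


def amalgamate_events(
    events: list[SceEvent],
    n_informative: int | dict[str, int] = 0,
    min_count: int = 2,
) -> list[RecurrentEvent]:
    """Group events recurring over the same interval across libraries.

    Events whose intervals mutually overlap by at least 1 bp are grouped by
    single linkage; groups with at least ``min_count`` events are reported
    with the intersected interval and the occurrence count.
    ``n_informative`` (total or per-chromosome library count) scales the
    reported fraction; 0 leaves the fraction at NaN.
    """
    out: list[RecurrentEvent] = []
    for cluster in _cluster_by_overlap(events):
        if len(cluster) < min_count:
            continue
        lo, hi = _intersection(cluster)
        chrom = cluster[0].chrom
        n_inf = (n_informative.get(chrom, 0)
                 if isinstance(n_informative, dict) else n_informative)
        out.append(RecurrentEvent(
            chrom=chrom, start=lo, end=hi, count=len(cluster),
            libraries=sorted({e.library_id for e in cluster}),
            fraction_informative=(len(cluster) / n_inf if n_inf else float("nan")),
        ))
    return out


def call_misorientations(
    events: list[SceEvent],
    n_informative: int | dict[str, int],
    chrom_lengths: dict[str, int] | None = None,
    min_libraries: int = 2,
) -> list[MisorientationCall]:
    """Call reference misorientations from candidate events across libraries.

    A misoriented segment has *two* boundaries (entry and exit, or one when
    it reaches a chromosome end), so boundary events are first clustered by
    overlap across libraries and then paired left-to-right into segments.
    ``n_informative`` is the number of libraries able to show the flip over
    each chromosome: for diploid WW<->CC calls that is the homozygously
    inherited libraries (a WC chromosome reads WC either way and is blind
    to misorientation), for haploid chromosomes every state-callable one.
    Diploid segments are reported when at least ``min_libraries`` show the
    flip (an isolated WW->CC event is most likely a segmentation artifact);
    on haploid chromosomes, where a single-library switch is a genuine SCE,
    boundary clusters must recur in *all* informative libraries.
    """

    def informative_for(chrom: str) -> int:
        if isinstance(n_informative, dict):
            return int(n_informative.get(chrom, 0))
        return int(n_informative)

    def paired_calls(pool: list[SceEvent], chrom: str, n_inf: int,
                     require_full: bool, note: str) -> list[MisorientationCall]:
        clusters = _cluster_by_overlap([e for e in pool if e.chrom == chrom])
        kept = []
        for c in clusters:
            libs = {e.library_id for e in c}
            if require_full:
                if len(libs) >= n_inf:
                    kept.append((c, libs))
            elif len(libs) >= min_libraries:
                kept.append((c, libs))
            else:
                log.info("boundary on %s seen in %d library(ies); suppressed",
                         chrom, len(libs))
        kept.sort(key=lambda t: _intersection(t[0])[0])
        out = []
        for i in range(0, len(kept) - 1, 2):
            (left, libs_l), (right, libs_r) = kept[i], kept[i + 1]
            libs = libs_l | libs_r
            out.append(MisorientationCall(
                chrom=chrom,
                start=min(e.start for e in left),
                end=max(e.end for e in right),
                concordance=100.0 * min(len(libs), n_inf) / n_inf,
                n_libraries=len(libs), note=note,
            ))
        if len(kept) % 2 == 1:  # segment reaching the chromosome end
            tail, libs = kept[-1]
            length = (chrom_lengths or {}).get(chrom)
            if length is not None:
                out.append(MisorientationCall(
                    chrom=chrom, start=min(e.start for e in tail), end=length,
                    concordance=100.0 * min(len(libs), n_inf) / n_inf,
                    n_libraries=len(libs), note=note + ";terminal",
                ))
        return out

    calls: list[MisorientationCall] = []
    diploid = [e for e in events if e.kind == MISORIENTATION_CANDIDATE]
    haploid = [e for e in events if e.kind == HAPLOID_SWITCH]
    for pool, require_full, note in ((diploid, False, "WW<->CC"),
                                     (haploid, True, "haploid-paired-switch")):
        for chrom in sorted({e.chrom for e in pool}):
            n_inf = informative_for(chrom)
            if n_inf < min_libraries:
                log.info("%s: fewer than %d informative libraries; "
                         "misorientation calling suppressed", chrom,
                         min_libraries)
                continue
            calls.extend(paired_calls(pool, chrom, n_inf, require_full, note))
    return calls


def detect_cnv_segments(
    counts: BinnedCounts,
    chrom: str,
    library_mean_depth: float | None = None,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[CnvSegment]:
    """Segment a chromosome's total-depth track into copy-number segments.

    Relative depth per bin is total count over the library per-bin mean
    (the trailing partial bin is scaled by its width); segments come from
    the same CBS backend as transition detection and the copy estimate is
    round(2 x segment relative depth).  Segments tile the chromosome.
    """
    if library_mean_depth is None:
        all_totals = np.concatenate([counts.totals(c) for c in counts.chromosomes])
        library_mean_depth = float(all_totals.mean())
    if library_mean_depth <= 0:
        raise ValueError("library has zero depth")
    totals = counts.totals(chrom).astype(float)
    n_bins = len(totals)
    length = counts.chrom_lengths[chrom]
    frac = np.ones(n_bins)
    last_width = length - (n_bins - 1) * counts.bin_size
    if n_bins > 0 and 0 < last_width < counts.bin_size:
        frac[-1] = last_width / counts.bin_size
    rel = totals / (library_mean_depth * frac)
    if n_bins < 2:
        mean = float(rel.mean()) if n_bins else 0.0
        return [CnvSegment(chrom, 0, length, mean, round_half_away(2 * mean))]
    rng = np.random.default_rng([seed, 4])
    pieces = cbs_segment(rel, alpha=alpha, n_perm=n_perm, rng=rng)
    segments: list[CnvSegment] = []
    for a, b in pieces:
        mean = float(rel[a:b].mean())
        copy = max(0, round_half_away(2.0 * mean))
        start = a * counts.bin_size
        end = min(length, b * counts.bin_size)
        if segments and segments[-1].copy_number == copy:
            prev = segments[-1]
            w_prev = prev.end - prev.start
            w_new = end - start
            merged_depth = (prev.relative_depth * w_prev + mean * w_new) / (w_prev + w_new)
            segments[-1] = CnvSegment(chrom, prev.start, end, merged_depth, copy)
        else:
            segments.append(CnvSegment(chrom, start, end, mean, copy))
    return segments
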