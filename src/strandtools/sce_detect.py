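"""Localization of template-strand transitions within single libraries.

A sister chromatid exchange changes the per-bin ratio (W-C)/(W+C) from one
integer level (+1 WW, 0 WC, -1 CC) to another somewhere along a chromosome.
The detector works in three passes:

1. gross pass: mask deviant-depth bins, compute the ratio track, and
   segment it with circular binary segmentation (CBS); a changepoint is
   first localized to the two-bin interval around the segment boundary
   (400 kb at the default 200 kb bins);
2. iterative refinement: the interval is padded by half its width on each
   side, its reads are re-binned at one fifth of the interval width (80 kb
   on the first iteration) and re-segmented; iteration stops when fewer
   than 50 reads remain in the interval or the re-segmentation no longer
   finds exactly one changepoint;
3. read-level walker: scanning from the homozygous side, the first
   opposite-template read is accepted if the 10 preceding reads all carry
   the homozygous template and at least 4 of the 20 reads from the
   candidate onward carry the opposite template, giving a final interval
   between two individual reads.

Events are classified by their flanking states: homozygous <-> heterozygous
transitions are SCEs, WW <-> CC transitions are reference-misorientation
candidates, and any switch on a copy-number-1 chromosome is a haploid
switch (which an SCE and a misorientation produce alike).
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_binning import CRICK, WATSON, BinnedCounts, ReadSet
from .strand_state import PloidyCall, ratio_level

log = logging.getLogger("strandtools")

DEFAULT_SD_THRESHOLD = 0.2
DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 1000
DEFAULT_MIN_REFINE_READS = 50

SCE = "SCE"
MISORIENTATION_CANDIDATE = "misorientation-candidate"
HAPLOID_SWITCH = "haploid-switch"

_DIPLOID_LEVEL_STATE = {1: "WW", 0: "WC", -1: "CC"}
_HAPLOID_LEVEL_STATE = {1: WATSON, -1: CRICK, 0: "unknown"}


# ---------------------------------------------------------------------------
# ratio track and bin filtering

@dataclass
class RatioTrack:
    """Per-bin raw ratio, rounded level, and excluded-bin mask for one chromosome."""

    chrom: str
    bin_size: int
    raw: np.ndarray        # NaN where masked or empty
    level: np.ndarray      # int in {-1, 0, 1}; meaningless where masked
    excluded: np.ndarray   # True = bin not used for segmentation

    @property
    def valid_bins(self) -> np.ndarray:
        return np.flatnonzero(~self.excluded)


def filter_bins(
    counts: BinnedCounts, sd_threshold: float = DEFAULT_SD_THRESHOLD
) -> dict[str, np.ndarray]:
    """Mask bins whose total depth deviates grossly from their chromosome's.

    Each non-empty bin's total is compared to the median of its own
    chromosome's non-empty bins (so a legitimately half-depth monosome is
    not wiped out wholesale); the deviation is masked when it exceeds
    ``max(sd_threshold * SD, 3 * sqrt(chromosome median))``, where SD is
    the library-wide spread of bin totals around their chromosome medians.
    The SD term scales with the overdispersion of real libraries while the
    square-root floor keeps ordinary counting noise unmasked.  A non-finite
    threshold masks nothing.  Empty bins are never masked here (they are
    skipped as uninformative downstream).
    """
    totals = {c: counts.totals(c) for c in counts.chromosomes}
    masks = {c: np.zeros(len(t), dtype=bool) for c, t in totals.items()}
    if not np.isfinite(sd_threshold):
        return masks
    centers = {}
    residuals = []
    for chrom, t in totals.items():
        nonempty = t[t > 0]
        if len(nonempty) == 0:
            continue
        centers[chrom] = float(np.median(nonempty))
        residuals.append(nonempty - centers[chrom])
    pooled = np.concatenate(residuals) if residuals else np.array([])
    if len(pooled) < 2:
        return masks
    spread = float(pooled.std())
    for chrom, t in totals.items():
        if chrom not in centers:
            continue
        center = centers[chrom]
        band = max(sd_threshold * spread, 3.0 * math.sqrt(center))
        masks[chrom] = (t > 0) & (np.abs(t - center) > band)
    return masks


def compute_ratio_track(
    counts: BinnedCounts, chrom: str, excluded: np.ndarray | None = None
) -> RatioTrack:
    """Raw and level-rounded (W-C)/(W+C) per bin; empty bins are masked."""
    w = counts.watson[chrom].astype(float)
    c = counts.crick[chrom].astype(float)
    total = w + c
    if excluded is None:
        excluded = np.zeros(len(total), dtype=bool)
    excluded = excluded | (total == 0)
    raw = np.full(len(total), np.nan)
    np.divide(w - c, total, out=raw, where=total > 0)
    level = np.array([ratio_level(r) if np.isfinite(r) else 0 for r in raw])
    raw[excluded] = np.nan
    return RatioTrack(chrom=chrom, bin_size=counts.bin_size, raw=raw,
                      level=level, excluded=excluded)


# ---------------------------------------------------------------------------
# circular binary segmentation

#: smallest allowed arc (and complement) in bins.  Single-bin arcs are
#: forbidden: isolating one outlier bin is permutation-invariant, which
#: degenerates the permutation test, and a one-bin feature is below the
#: method's resolution anyway.
MIN_ARC_WIDTH = 2


def _max_arc_stat(x: np.ndarray) -> tuple[float, int, int]:
    """Maximal arc-vs-complement mean-shift statistic over all arcs (i, j)."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    k = np.arange(n + 1, dtype=float)[None, :] - np.arange(n + 1, dtype=float)[:, None]
    d = s[None, :] - s[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.abs(d / k - (total - d) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
    stat[_invalid_arcs(n)] = -np.inf
    idx = int(np.argmax(stat))
    i, j = divmod(idx, n + 1)
    return float(stat[i, j]), i, j


def _invalid_arcs(n: int) -> np.ndarray:
    """Arcs whose cut would create a run below MIN_ARC_WIDTH bins."""
    idx = np.arange(n + 1)
    k = idx[None, :] - idx[:, None]
    bad = (k < MIN_ARC_WIDTH) | (k > n - MIN_ARC_WIDTH)
    # edge pieces [0, i) and [j, n) must also be empty or >= MIN_ARC_WIDTH
    bad |= ((idx[:, None] > 0) & (idx[:, None] < MIN_ARC_WIDTH))
    bad |= ((idx[None, :] < n) & (idx[None, :] > n - MIN_ARC_WIDTH))
    return bad


def _perm_exceedances(
    x: np.ndarray, observed: float, n_perm: int, rng: np.random.Generator,
    stop_at: int,
) -> int:
    """Count permutations whose max arc statistic strictly exceeds ``observed``.

    Stops early once ``stop_at`` exceedances are reached (the split can no
    longer be significant).  Ties count for the null side; on the discrete
    ratio tracks of clean libraries every permutation that merely re-creates
    the observed contiguous arrangement ties rather than beats it.
    """
    n = len(x)
    k = np.arange(n + 1, dtype=float)[None, :] - np.arange(n + 1, dtype=float)[:, None]
    invalid = _invalid_arcs(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(1.0 / k + 1.0 / (n - k))
        inv_k = 1.0 / k
        inv_nk = 1.0 / (n - k)
    count = 0
    done = 0
    block = max(1, min(64, int(2e6 / max(1, n * n))))
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = np.empty((b, n))
        for t in range(b):
            perms[t] = rng.permutation(x)
        s = np.concatenate([np.zeros((b, 1)), np.cumsum(perms, axis=1)], axis=1)
        total = s[:, -1][:, None, None]
        d = s[:, None, :] - s[:, :, None]
        with np.errstate(invalid="ignore"):
            stat = np.abs(d * inv_k - (total - d) * inv_nk) / denom
        stat[:, invalid] = -np.inf
        count += int(np.sum(stat.reshape(b, -1).max(axis=1) > observed + 1e-12))
        done += b
        if count >= stop_at:
            break
    return count


def cbs_segment(
    x: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Circular binary segmentation of a 1-D signal.

    Recursively splits at the most significant arc whose permutation
    p-value is below ``alpha``; returns half-open index segments covering
    ``range(len(x))``.  Constant stretches are never split.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    stop_at = max(1, int(math.ceil(alpha * n_perm)))
    segments: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        seg = x[lo:hi]
        if n < 2 * MIN_ARC_WIDTH or np.all(seg == seg[0]):
            segments.append((lo, hi))
            return
        observed, i, j = _max_arc_stat(seg)
        if not np.isfinite(observed) or observed <= 0:
            segments.append((lo, hi))
            return
        count = _perm_exceedances(seg, observed, n_perm, rng, stop_at)
        if count >= stop_at:  # p >= alpha
            segments.append((lo, hi))
            return
        cuts = sorted({lo, lo + i, lo + j, hi})
        for a, b in zip(cuts[:-1], cuts[1:]):
            recurse(a, b)

    recurse(0, len(x))
    segments.sort()
    return segments


@dataclass
class Segment:
    """A maximal run of bins at one rounded ratio level (original bin indices)."""

    first_bin: int
    last_bin: int
    level: int
    mean: float


def segment_track(
    track: RatioTrack,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> tuple[list[Segment], list[tuple[int, int]]]:
    """Segment the unmasked ratio track into integer-level runs.

    CBS segments of the raw ratio are rounded to the nearest level in
    {-1, 0, 1} and equal-level neighbours merged, enforcing the constraint
    that only WW/WC/CC calls exist.  Returns the merged segments and the
    changepoints as two-bin index pairs (last bin of the left segment,
    first bin of the right segment) in original bin coordinates.
    """
    valid = track.valid_bins
    if len(valid) < 2:
        if len(valid) == 0:
            log.warning("%s: all bins masked or empty; no segments", track.chrom)
            return [], []
        v = valid[0]
        seg = Segment(v, v, ratio_level(track.raw[v]), float(track.raw[v]))
        return [seg], []
    x = track.raw[valid]
    pieces = cbs_segment(x, alpha=alpha, n_perm=n_perm, rng=rng)
    merged: list[Segment] = []
    for a, b in pieces:
        mean = float(x[a:b].mean())
        level = ratio_level(mean)
        if merged and merged[-1].level == level:
            prev = merged[-1]
            lo_v = np.flatnonzero(valid == prev.first_bin)[0]
            new_mean = float(x[lo_v:b].mean())
            merged[-1] = Segment(prev.first_bin, int(valid[b - 1]), level, new_mean)
        else:
            merged.append(Segment(int(valid[a]), int(valid[b - 1]), level, mean))
    changepoints = [
        (merged[i].last_bin, merged[i + 1].first_bin) for i in range(len(merged) - 1)
    ]
    return merged, changepoints


# ---------------------------------------------------------------------------
# iterative refinement

def _bin_interval_reads(
    positions: np.ndarray, strands: np.ndarray, lo: int, hi: int, bin_size: int
) -> tuple[np.ndarray, np.ndarray]:
    n_bins = max(1, math.ceil((hi - lo) / bin_size))
    inside = (positions >= lo) & (positions < hi)
    idx = ((positions[inside] - lo) // bin_size).astype(int)
    w = np.bincount(idx[strands[inside] == WATSON], minlength=n_bins)
    c = np.bincount(idx[strands[inside] == CRICK], minlength=n_bins)
    return w[:n_bins], c[:n_bins]


def refine_interval(
    interval: tuple[int, int],
    positions: np.ndarray,
    strands: np.ndarray,
    chrom_length: int,
    subdivision: int = 5,
    min_reads: int = DEFAULT_MIN_REFINE_READS,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    rng: np.random.Generator | None = None,
) -> tuple[tuple[int, int], list[tuple[int, int]], bool]:
    """Iteratively shrink a changepoint interval by re-binning its reads.

    Each iteration pads the current interval by half its width per side
    (clipped to the chromosome), re-bins the padded region at one
    ``subdivision``-th of the current interval width, re-segments, and keeps
    the new two-bin changepoint interval.  Stops when the interval holds
    fewer than ``min_reads`` reads or re-segmentation does not find exactly
    one changepoint.  Returns ``(interval, trace, refined)`` where the trace
    lists every accepted interval (input first) and ``refined`` is False
    when no iteration could improve on the input.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lo, hi = int(interval[0]), int(interval[1])
    trace = [(lo, hi)]
    refined = False
    order = np.argsort(positions, kind="mergesort")
    positions = positions[order]
    strands = strands[order]
    while True:
        n_inside = int(np.sum((positions >= lo) & (positions < hi)))
        if n_inside < min_reads:
            break
        width = hi - lo
        pad = width // 2
        plo = max(0, lo - pad)
        phi = min(chrom_length, hi + pad)
        bin_size = max(1, width // subdivision)
        w, c = _bin_interval_reads(positions, strands, plo, phi, bin_size)
        total = w + c
        valid = np.flatnonzero(total > 0)
        if len(valid) < 2:
            break
        raw = (w[valid] - c[valid]) / total[valid]
        pieces = cbs_segment(raw, alpha=alpha, n_perm=n_perm, rng=rng)
        levels = [ratio_level(float(raw[a:b].mean())) for a, b in pieces]
        # merge adjacent equal-level runs, in valid-bin index space
        run_bounds: list[list[int]] = []
        prev_level: int | None = None
        for (a, b), lev in zip(pieces, levels):
            if prev_level is None or lev != prev_level:
                run_bounds.append([a, b])
            else:
                run_bounds[-1][1] = b
            prev_level = lev
        if len(run_bounds) != 2:
            break
        left_last = valid[run_bounds[0][1] - 1]
        right_first = valid[run_bounds[1][0]]
        new_lo = plo + int(left_last) * bin_size
        new_hi = min(phi, plo + (int(right_first) + 1) * bin_size)
        if (new_lo, new_hi) == (lo, hi) or new_hi - new_lo > hi - lo:
            break
        lo, hi = new_lo, new_hi
        trace.append((lo, hi))
        refined = True
        if len(trace) > 40:  # defensive cap; widths shrink geometrically
            break
    if not refined:
        log.debug("interval %s not refined", interval)
    return (lo, hi), trace, refined


# ---------------------------------------------------------------------------
# read-level walker

def walker_refine(
    positions: np.ndarray,
    strands: np.ndarray,
    homozygous_strand: str,
    from_left: bool = True,
    n_preceding: int = 10,
    n_following: int = 20,
    min_opposite: int = 4,
    start_index: int = 0,
) -> tuple[tuple[int, int], bool]:
    """Refine a transition to the gap between two reads.

    Scans the (position-sorted) reads from the homozygous side and accepts
    the first opposite-template read whose ``n_preceding`` preceding reads
    (in scan order, as many as exist) are all homozygous-template and whose
    following window of up to ``n_following`` reads (candidate included)
    contains at least ``min_opposite`` opposite-template reads (scaled as
    ceil(min_opposite/n_following x window) when fewer reads remain).
    Returns the genomic interval between the last homozygous-template read
    and the accepted read, and an acceptance flag; when no candidate passes
    the input's outer span is returned unrefined.  Reads before
    ``start_index`` (in scan order) only provide context for the checks and
    are never accepted as candidates, so callers can hand over flanking
    reads without widening the searched region.
    """
    order = np.argsort(positions, kind="mergesort")
    pos = positions[order]
    strs = strands[order]
    if not from_left:
        pos = pos[::-1]
        strs = strs[::-1]
    opposite = CRICK if homozygous_strand == WATSON else WATSON
    n = len(pos)
    for idx in np.flatnonzero(strs == opposite):
        if idx == 0 or idx < start_index:
            continue  # context-only read, or no preceding read to verify
        pre = strs[max(0, idx - n_preceding): idx]
        if not np.all(pre == homozygous_strand):
            continue
        window = strs[idx: idx + n_following]
        need = (min_opposite if len(window) >= n_following
                else max(1, math.ceil(min_opposite / n_following * len(window))))
        if int(np.sum(window == opposite)) < need:
            continue
        a, b = int(pos[idx - 1]), int(pos[idx])
        return (min(a, b), max(a, b)), True
    if n == 0:
        return (0, 0), False
    return (int(pos.min()), int(pos.max())), False


# ---------------------------------------------------------------------------
# whole-library detection

@dataclass
class SceEvent:
    """A localized template-state transition in one library."""

    library_id: str
    chrom: str
    start: int
    end: int
    left_state: str
    right_state: str
    kind: str  # SCE | misorientation-candidate | haploid-switch
    gross_interval: tuple[int, int] = (0, 0)
    refined_interval: tuple[int, int] = (0, 0)
    trace: list[tuple[int, int]] = field(default_factory=list)
    walker_accepted: bool = True
    terminal: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def classify_event(left_state: str, right_state: str, copy_number: int) -> str:
    if copy_number == 1:
        return HAPLOID_SWITCH
    if {left_state, right_state} == {"WW", "CC"}:
        return MISORIENTATION_CANDIDATE
    return SCE


def detect_events(
    reads: ReadSet,
    counts: BinnedCounts,
    ploidy: list[PloidyCall] | None = None,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    min_refine_reads: int = DEFAULT_MIN_REFINE_READS,
    seed: int = 0,
    walker_context: int = 30,
) -> list[SceEvent]:
    """Detect and localize all template-state transitions of one library.

    Per chromosome: bin filter -> ratio track -> CBS -> per changepoint,
    iterative refinement then the read-level walker.  Chromosomes with
    called copy number above 2 are skipped with a warning (transitions are
    not reliably separable there); a failure on one chromosome never aborts
    the library.
    """
    copy_of = {p.chrom: p.copy_number for p in (ploidy or [])}
    masks = filter_bins(counts, sd_threshold=sd_threshold)
    events: list[SceEvent] = []
    for chrom, length in counts.chrom_lengths.items():
        n_copies = copy_of.get(chrom, 2)
        if n_copies > 2:
            log.warning("%s: copy number %d > 2; transition detection skipped",
                        chrom, n_copies)
            continue
        if n_copies == 0:
            continue
        rng = np.random.default_rng([seed, zlib.crc32(chrom.encode())])
        try:
            track = compute_ratio_track(counts, chrom, excluded=masks[chrom])
            segments, changepoints = segment_track(
                track, alpha=alpha, n_perm=n_perm, rng=rng)
        except Exception:  # pragma: no cover - defensive per-chromosome guard
            log.exception("%s: segmentation failed; chromosome skipped", chrom)
            continue
        if not changepoints:
            continue
        df = reads.for_chromosome(chrom)
        positions = df["start"].to_numpy()
        strands = df["strand"].to_numpy()
        order = np.argsort(positions, kind="mergesort")
        positions = positions[order]
        strands = strands[order]
        state_of = _HAPLOID_LEVEL_STATE if n_copies == 1 else _DIPLOID_LEVEL_STATE
        for seg_idx, (left_bin, right_bin) in enumerate(changepoints):
            left_seg = segments[seg_idx]
            right_seg = segments[seg_idx + 1]
            left_state = state_of[left_seg.level]
            right_state = state_of[right_seg.level]
            gross = (left_bin * counts.bin_size,
                     min(length, (right_bin + 1) * counts.bin_size))
            refined, trace, _ = refine_interval(
                gross, positions, strands, length,
                min_reads=min_refine_reads, alpha=alpha, n_perm=n_perm, rng=rng)
            # walker scans from the homozygous flank
            if n_copies == 1 or right_state == "WC":
                from_left = True
                homo = WATSON if left_state in ("WW", WATSON) else CRICK
            elif left_state == "WC":
                from_left = False
                homo = WATSON if right_state in ("WW", WATSON) else CRICK
            else:  # WW <-> CC candidate: scan from the left flank
                from_left = True
                homo = WATSON if left_state == "WW" else CRICK
            i0 = int(np.searchsorted(positions, refined[0], side="left"))
            i1 = int(np.searchsorted(positions, refined[1], side="right"))
            w0 = max(0, i0 - walker_context)
            w1 = min(len(positions), i1 + walker_context)
            start_index = (i0 - w0) if from_left else (w1 - i1)
            interval, accepted = walker_refine(
                positions[w0:w1], strands[w0:w1], homo, from_left=from_left,
                start_index=start_index)
            if not accepted:
                interval = refined
            events.append(SceEvent(
                library_id=reads.library_id,
                chrom=chrom,
                start=int(interval[0]),
                end=int(interval[1]),
                left_state=left_state,
                right_state=right_state,
                kind=classify_event(left_state, right_state, n_copies),
                gross_interval=gross,
                refined_interval=refined,
                trace=trace,
                walker_accepted=accepted,
                terminal=(gross[0] <= 0 or gross[1] >= length),
            ))
    return events


def events_to_frame(events: list[SceEvent]) -> pd.DataFrame:
    rows = [
        {
            "library": e.library_id, "chrom": e.chrom, "start": e.start,
            "end": e.end, "left_state": e.left_state,
            "right_state": e.right_state, "kind": e.kind,
            "gross_start": e.gross_interval[0], "gross_end": e.gross_interval[1],
            "walker_accepted": e.walker_accepted, "terminal": e.terminal,
        }
        for e in events
    ]
    return pd.DataFrame(rows, columns=[
        "library", "chrom", "start", "end", "left_state", "right_state",
        "kind", "gross_start", "gross_end", "walker_accepted", "terminal"])
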