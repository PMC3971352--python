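"""Standard-format outputs: UCSC BED tracks, summary tables, ideograms."""

from __future__ import annotations

import hashlib
import json
import logging
import os

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io_binning import BinnedCounts
from .rearrange import CnvSegment, MisorientationCall, RecurrentEvent
from .sce_detect import SceEvent
from .strand_state import BackgroundMetric, StateCall, segregation_summary

log = logging.getLogger("strandtools")


def write_event_bed(events: list[SceEvent], path, track_name: str) -> None:
    """One record per event (0-based half-open), name = state transition,
    score = walker acceptance (1/0); with a UCSC track line."""
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}" description="template-strand '
                 f'transitions" visibility=2\n')
        for e in sorted(events, key=lambda e: (e.chrom, e.start, e.end)):
            name = f"{e.left_state}-{e.right_state}.{e.kind}"
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{name}\t"
                     f"{int(e.walker_accepted)}\t.\n")


def read_event_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("track"):
                continue
            chrom, start, end, name, score, strand = line.rstrip("\n").split("\t")
            rows.append({"chrom": chrom, "start": int(start), "end": int(end),
                         "name": name, "score": int(score)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def write_recurrent_bed(events: list[RecurrentEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write('track name="recurrent_events" description="intervals with '
                 'events in multiple libraries" visibility=2\n')
        for e in sorted(events, key=lambda e: (e.chrom, e.start)):
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\trecurrent_n{e.count}\t"
                     f"{e.count}\t.\n")


def write_cnv_bed(segments: list[CnvSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write('track name="cnv_segments" description="read-depth copy '
                 'number" visibility=2\n')
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tcopy{s.copy_number}\t"
                     f"{s.copy_number}\t.\n")


def write_misorientations_csv(calls: list[MisorientationCall], path) -> None:
    rows = [{"chrom": m.chrom, "start": m.start, "end": m.end,
             "concordance": round(m.concordance, 1),
             "n_libraries": m.n_libraries, "note": m.note} for m in calls]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "concordance",
                                "n_libraries", "note"]).to_csv(path, index=False)


def inter_event_distances(events: list[SceEvent]) -> pd.DataFrame:
    """Minimal distance from each event to the nearest other event on the
    same chromosome, pooled across libraries (clustered events hint at
    recurrent damage or rearrangement)."""
    rows = []
    by_chrom: dict[str, list[SceEvent]] = {}
    for e in events:
        by_chrom.setdefault(e.chrom, []).append(e)
    for chrom, evs in sorted(by_chrom.items()):
        mids = sorted((e.start + e.end) // 2 for e in evs)
        for i, m in enumerate(mids):
            neighbours = [abs(m - other) for j, other in enumerate(mids) if j != i]
            if neighbours:
                rows.append({"chrom": chrom, "midpoint": m,
                             "nearest_event_bp": min(neighbours)})
    return pd.DataFrame(rows, columns=["chrom", "midpoint", "nearest_event_bp"])


def write_summary(
    out_dir: str,
    state_calls: dict[str, list[StateCall]],
    backgrounds: dict[str, BackgroundMetric],
    events: list[SceEvent],
    misorientations: list[MisorientationCall] | None = None,
    recurrent: list[RecurrentEvent] | None = None,
) -> list[str]:
    """Write the machine-readable summary tables; returns the file list."""
    written = []

    lib_rows = []
    for lib in sorted(state_calls):
        b = backgrounds.get(lib)
        n_events = sum(1 for e in events if e.library_id == lib)
        lib_rows.append({
            "library": lib,
            "background_percent": (round(b.background_percent, 3)
                                   if b and b.defined else ""),
            "background_defined": bool(b and b.defined),
            "n_homozygous_chromosomes": b.n_homozygous if b else 0,
            "n_events": n_events,
        })
    path = os.path.join(out_dir, "library_summary.csv")
    pd.DataFrame(lib_rows).to_csv(path, index=False)
    written.append(path)

    call_rows = []
    for lib in sorted(state_calls):
        for call in state_calls[lib]:
            call_rows.append({"library": lib, "chrom": call.chrom,
                              "state": call.state, "watson": call.watson,
                              "crick": call.crick})
    path = os.path.join(out_dir, "state_calls.csv")
    pd.DataFrame(call_rows).to_csv(path, index=False)
    written.append(path)

    if len(state_calls) >= 2:
        seg = segregation_summary([state_calls[lib] for lib in sorted(state_calls)])
        path = os.path.join(out_dir, "segregation_summary.csv")
        seg.to_csv(path, index=False)
        written.append(path)

    path = os.path.join(out_dir, "inter_event_distances.csv")
    inter_event_distances(events).to_csv(path, index=False)
    written.append(path)

    if misorientations is not None:
        path = os.path.join(out_dir, "misorientations.csv")
        write_misorientations_csv(misorientations, path)
        written.append(path)
    if recurrent is not None:
        path = os.path.join(out_dir, "recurrent_events.bed")
        write_recurrent_bed(recurrent, path)
        written.append(path)
    return written


def plot_ideogram(
    counts: BinnedCounts,
    events: list[SceEvent],
    background: BackgroundMetric | None,
    path,
) -> None:
    """One panel per chromosome: Watson density left of the axis, Crick
    right, events marked with arrowheads, library background printed."""
    chroms = counts.chromosomes
    fig, axes = plt.subplots(1, max(1, len(chroms)),
                             figsize=(1.2 * max(1, len(chroms)), 6),
                             sharey=False)
    if len(chroms) == 1:
        axes = [axes]
    max_len = max(counts.chrom_lengths.values())
    for ax, chrom in zip(axes, chroms):
        w = counts.watson[chrom].astype(float)
        c = counts.crick[chrom].astype(float)
        scale = max(1.0, max(w.max(), c.max()))
        y = (np.arange(len(w)) + 0.5) * counts.bin_size
        ax.barh(y, -w / scale, height=counts.bin_size, color="#E69F00")
        ax.barh(y, c / scale, height=counts.bin_size, color="#0072B2")
        ax.axvline(0.0, color="0.4", lw=0.5)
        for e in events:
            if e.chrom != chrom:
                continue
            mid = (e.start + e.end) / 2
            ax.plot([-1.05], [mid], marker=">", color="red", ms=5,
                    clip_on=False)
        ax.set_ylim(max_len, 0)
        ax.set_xlim(-1.1, 1.1)
        ax.set_xticks([])
        ax.set_yticks([])
        ax.set_title(chrom, fontsize=7)
    label = ("background n/a" if background is None or not background.defined
             else f"background {background.background_percent:.1f}%")
    fig.suptitle(f"{counts.library_id}  ({label})", fontsize=9)
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str, files: list[str], path=None) -> str:
    """JSON manifest of produced files with sha256 checksums."""
    if path is None:
        path = os.path.join(out_dir, "manifest.json")
    entries = {}
    for f in sorted(set(files)):
        rel = os.path.relpath(f, out_dir)
        entries[rel] = sha256_file(f)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
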