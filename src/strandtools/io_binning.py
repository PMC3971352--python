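"""Read ingestion, filtering, and directional binning.

Strand-seq libraries contain only parental template strands, so the aligned
strand of every read is informative: plus-strand alignments report a Crick
(top-strand) template, minus-strand alignments a Watson (bottom-strand)
template.  This module loads aligned reads from BAM or from a plain-text
strand BED dialect, applies duplicate/quality filters, and reduces a library
to per-bin Watson/Crick counts -- the working signal for every downstream
stage.

Coordinates are 0-based half-open everywhere internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger("strandtools")

WATSON = "W"
CRICK = "C"

#: columns of the read table inside a :class:`ReadSet`
READ_COLUMNS = ["chrom", "start", "strand", "mapq", "duplicate"]

#: default bin width in bp
DEFAULT_BIN_SIZE = 200_000

#: default mapping-quality cutoff (the method thresholds on quality without
#: stating a value; 10 removes most multi-mappers)
DEFAULT_MIN_QUALITY = 10

#: modelled read length in bp (reads are treated as short point intervals)
READ_LENGTH = 50


@dataclass
class ReadSet:
    """Strand-labelled aligned reads of one library.

    ``reads`` is a DataFrame with columns ``chrom, start, strand, mapq,
    duplicate``, sorted by (chrom, start).  ``strand`` is ``"W"`` or ``"C"``.
    """

    library_id: str
    reads: pd.DataFrame
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in READ_COLUMNS if c not in self.reads.columns]
        if missing:
            raise ValueError(f"read table missing columns {missing}")
        bad = set(self.reads["chrom"].unique()) - set(self.chrom_lengths)
        if bad:
            first = self.reads[self.reads["chrom"].isin(bad)].iloc[0]
            raise ValueError(
                f"read at {first['chrom']}:{first['start']} maps to a "
                f"chromosome absent from the length table ({sorted(bad)})"
            )
        self.reads = self.reads.sort_values(
            ["chrom", "start"], kind="mergesort"
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.reads)

    def for_chromosome(self, chrom: str) -> pd.DataFrame:
        return self.reads[self.reads["chrom"] == chrom]


@dataclass
class BinnedCounts:
    """Per-bin Watson/Crick read counts for one library.

    One array pair per chromosome; bin ``i`` covers
    ``[i*bin_size, (i+1)*bin_size)`` with the trailing partial bin kept.
    """

    bin_size: int
    watson: dict[str, np.ndarray]
    crick: dict[str, np.ndarray]
    chrom_lengths: dict[str, int]
    library_id: str = ""

    @property
    def chromosomes(self) -> list[str]:
        return list(self.watson)

    def n_bins(self, chrom: str) -> int:
        return len(self.watson[chrom])

    def totals(self, chrom: str) -> np.ndarray:
        return self.watson[chrom] + self.crick[chrom]

    def chrom_sums(self, chrom: str) -> tuple[int, int]:
        return int(self.watson[chrom].sum()), int(self.crick[chrom].sum())


def read_chrom_table(path) -> dict[str, int]:
    """Read a two-column (name, length) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1], names=["chrom", "length"])
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))


def write_chrom_table(chrom_lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")


def _load_bed(path, library_id: str) -> pd.DataFrame:
    rows = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
        skiprows=lambda i: False,
    )
    # tolerate a UCSC track line
    rows = rows[rows["chrom"] != "track"]
    strand = np.where(rows["strand"].astype(str) == "+", CRICK, WATSON)
    return pd.DataFrame(
        {
            "chrom": rows["chrom"].astype(str),
            "start": rows["start"].astype(np.int64),
            "strand": strand,
            "mapq": pd.to_numeric(rows["score"], errors="coerce").fillna(0).astype(int),
            "duplicate": False,
        }
    )


def _load_bam(path) -> tuple[pd.DataFrame, dict[str, int]]:
    chroms, starts, strands, mapqs, dups = [], [], [], [], []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        lengths = dict(zip(bam.references, bam.lengths))
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            chroms.append(aln.reference_name)
            starts.append(aln.reference_start)
            # plus-strand alignment = Crick template, minus = Watson
            strands.append(WATSON if aln.is_reverse else CRICK)
            mapqs.append(aln.mapping_quality)
            dups.append(aln.is_duplicate)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": pd.Series(starts, dtype=np.int64),
            "strand": pd.Series(strands, dtype=str),
            "mapq": pd.Series(mapqs, dtype=int),
            "duplicate": pd.Series(dups, dtype=bool),
        }
    )
    return df, lengths


def load_reads(
    path,
    min_quality: int = DEFAULT_MIN_QUALITY,
    drop_duplicates: bool = True,
    chrom_lengths: dict[str, int] | None = None,
    library_id: str | None = None,
) -> ReadSet:
    """Load one library from BAM or strand BED and apply read filters.

    Duplicate-flagged reads and reads below ``min_quality`` are removed.
    For BED input a chromosome-length table must be supplied; for BAM it is
    taken from the header unless overridden.
    """
    path = str(path)
    if library_id is None:
        library_id = path.rsplit("/", 1)[-1]
        for suffix in (".bam", ".bed"):
            if library_id.endswith(suffix):
                library_id = library_id[: -len(suffix)]
    if path.endswith(".bam"):
        df, header_lengths = _load_bam(path)
        if chrom_lengths is None:
            chrom_lengths = {str(k): int(v) for k, v in header_lengths.items()}
    else:
        if chrom_lengths is None:
            raise ValueError("BED input requires a chromosome-length table")
        df = _load_bed(path, library_id)

    n_raw = len(df)
    if drop_duplicates:
        df = df[~df["duplicate"]]
    df = df[df["mapq"] >= min_quality]
    if len(df) == 0:
        log.warning("library %s: no reads retained (of %d parsed)", library_id, n_raw)
    return ReadSet(library_id=library_id, reads=df.reset_index(drop=True),
                   chrom_lengths=chrom_lengths)


def write_reads_bed(reads: ReadSet, path) -> None:
    """Write a ReadSet as the strand BED dialect (chrom start end name score strand)."""
    df = reads.reads
    with open(path, "w") as fh:
        for i, (chrom, start, strand, mapq) in enumerate(
            zip(df["chrom"], df["start"], df["strand"], df["mapq"])
        ):
            bed_strand = "+" if strand == CRICK else "-"
            fh.write(
                f"{chrom}\t{start}\t{start + READ_LENGTH}\t"
                f"{reads.library_id}.{i}\t{mapq}\t{bed_strand}\n"
            )


def write_reads_bam(reads: ReadSet, path) -> None:
    """Write a ReadSet as a coordinate-sorted BAM with a minimal header."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": int(l)} for n, l in reads.chrom_lengths.items()],
    }
    tid = {n: i for i, n in enumerate(reads.chrom_lengths)}
    df = reads.reads.sort_values(["chrom", "start"], kind="mergesort")
    order = sorted(range(len(df)), key=lambda i: (tid[df["chrom"].iloc[i]], df["start"].iloc[i]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for j, i in enumerate(order):
            a = pysam.AlignedSegment()
            a.query_name = f"{reads.library_id}.{j}"
            a.query_sequence = "N" * READ_LENGTH
            a.reference_id = tid[df["chrom"].iloc[i]]
            a.reference_start = int(df["start"].iloc[i])
            a.mapping_quality = int(df["mapq"].iloc[i])
            a.cigarstring = f"{READ_LENGTH}M"
            a.flag = 16 if df["strand"].iloc[i] == WATSON else 0
            if bool(df["duplicate"].iloc[i]):
                a.flag |= 0x400
            out.write(a)
    pysam.index(str(path))


def bin_reads(reads: ReadSet, bin_size: int = DEFAULT_BIN_SIZE) -> BinnedCounts:
    """Count Watson/Crick reads per fixed-width bin.

    A read at position ``p`` contributes to bin ``floor(p / bin_size)``;
    the trailing partial bin is kept.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    watson: dict[str, np.ndarray] = {}
    crick: dict[str, np.ndarray] = {}
    grouped = dict(tuple(reads.reads.groupby("chrom", sort=False)))
    for chrom, length in reads.chrom_lengths.items():
        n_bins = max(1, math.ceil(length / bin_size))
        df = grouped.get(chrom)
        if df is None or len(df) == 0:
            watson[chrom] = np.zeros(n_bins, dtype=np.int64)
            crick[chrom] = np.zeros(n_bins, dtype=np.int64)
            continue
        idx = (df["start"].to_numpy() // bin_size).astype(np.int64)
        if idx.max() >= n_bins:
            raise ValueError(f"read beyond the end of {chrom} (length {length})")
        w = np.bincount(idx[df["strand"].to_numpy() == WATSON], minlength=n_bins)
        c = np.bincount(idx[df["strand"].to_numpy() == CRICK], minlength=n_bins)
        watson[chrom] = w.astype(np.int64)
        crick[chrom] = c.astype(np.int64)
    return BinnedCounts(
        bin_size=bin_size, watson=watson, crick=crick,
        chrom_lengths=dict(reads.chrom_lengths), library_id=reads.library_id,
    )
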