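"""Template-strand state calls, library background, ploidy and segregation.

A chromosome's template state is read off the chromosome-wide normalized
ratio r = (W - C) / (W + C): +1 when every read is Watson (WW inheritance),
-1 when every read is Crick (CC), 0 for an even mixture (WC).  The library
background metric -- the average frequency of spurious non-template-strand
reads on homozygously inherited chromosomes -- is the standard Strand-seq
library quality score.  Chromosome copy number is called from relative read
depth, and template segregation across libraries is summarized against the
1:2:1 expectation with a chi-square goodness-of-fit test and Holm
correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_binning import CRICK, WATSON, BinnedCounts

log = logging.getLogger("strandtools")

#: minimum reads on a chromosome/scaffold for an informative state call
DEFAULT_MIN_READS = 20

UNKNOWN = "unknown"
HOMOZYGOUS_STATES = {"WW", "CC", WATSON, CRICK}


@dataclass
class StateCall:
    chrom: str
    state: str  # WW | WC | CC | W | C | unknown
    watson: int
    crick: int
    informative: bool

    @property
    def total(self) -> int:
        return self.watson + self.crick


@dataclass
class BackgroundMetric:
    library_id: str
    background_percent: float | None  # None when undefined
    n_homozygous: int

    @property
    def defined(self) -> bool:
        return self.background_percent is not None


@dataclass
class PloidyCall:
    chrom: str
    relative_depth: float
    copy_number: int


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def ratio_level(r: float) -> int:
    """Round a ratio in [-1, 1] to the nearest of {-1, 0, 1}, ties away from zero."""
    if r >= 0.5:
        return 1
    if r <= -0.5:
        return -1
    return 0


def call_chromosome_state(
    counts: BinnedCounts,
    chrom: str,
    copy_number: int = 2,
    min_reads: int = DEFAULT_MIN_READS,
) -> StateCall:
    """Call the template state of one chromosome from its W/C read totals.

    Diploid chromosomes are called by rounding (W-C)/(W+C) to {-1, 0, 1}
    (CC / WC / WW); copy-number-1 chromosomes are called W or C by majority
    strand.  Fewer than ``min_reads`` reads (or zero reads) yields
    ``unknown`` rather than an error.
    """
    w, c = counts.chrom_sums(chrom)
    total = w + c
    if total < max(1, min_reads):
        return StateCall(chrom, UNKNOWN, w, c, informative=False)
    if copy_number == 1:
        if w == c:
            return StateCall(chrom, UNKNOWN, w, c, informative=False)
        return StateCall(chrom, WATSON if w > c else CRICK, w, c, informative=True)
    r = (w - c) / total
    state = {1: "WW", 0: "WC", -1: "CC"}[ratio_level(r)]
    return StateCall(chrom, state, w, c, informative=True)


def background_metric(library_id: str, calls: list[StateCall]) -> BackgroundMetric:
    """Pooled spurious-read frequency over homozygously inherited chromosomes.

    b = 100 x (opposite-strand reads on WW/CC/W/C chromosomes) / (all reads
    on those chromosomes).  Undefined (flagged, not dropped) when the library
    has no informative homozygous chromosome.
    """
    opposite = 0
    total = 0
    n_homo = 0
    for call in calls:
        if not call.informative or call.state not in HOMOZYGOUS_STATES:
            continue
        n_homo += 1
        total += call.total
        if call.state in ("WW", WATSON):
            opposite += call.crick
        else:
            opposite += call.watson
    if n_homo == 0 or total == 0:
        log.warning("library %s: background undefined (no homozygous chromosome)",
                    library_id)
        return BackgroundMetric(library_id, None, 0)
    return BackgroundMetric(library_id, 100.0 * opposite / total, n_homo)


def call_ploidy(counts: BinnedCounts) -> list[PloidyCall]:
    """Call integer chromosome copy number from relative read depth.

    Relative depth d = chromosome mean per-bin depth / library mean per-bin
    depth; copy number n = round(2 d) with halves away from zero, so d = 0.5
    gives a monosome and d = 1.5 a triploid chromosome.
    """
    if len(counts.chromosomes) < 2:
        raise ValueError("ploidy calling needs at least two chromosomes")
    all_totals = np.concatenate([counts.totals(c) for c in counts.chromosomes])
    lib_mean = all_totals.mean() if len(all_totals) else 0.0
    if lib_mean <= 0:
        raise ValueError("library has zero depth; cannot call ploidy")
    calls = []
    for chrom in counts.chromosomes:
        d = counts.totals(chrom).mean() / lib_mean
        calls.append(PloidyCall(chrom, float(d), round_half_away(2.0 * d)))
    return calls


def segregation_summary(
    calls_per_library: list[list[StateCall]],
    expected: tuple[float, float, float] = (1.0, 2.0, 1.0),
) -> pd.DataFrame:
    """Per-chromosome WW/WC/CC tallies with Holm-adjusted chi-square p-values.

    Tests each chromosome's (nWW, nWC, nCC) against the expected segregation
    ratio (default 1:2:1, from random chromatid segregation); p-values are
    Holm-adjusted across chromosomes.  Chromosomes with no informative
    diploid call are excluded (listed with NaN p).
    """
    if len(calls_per_library) < 2:
        raise ValueError("segregation summary needs at least two libraries")
    tallies: dict[str, dict[str, int]] = {}
    for calls in calls_per_library:
        for call in calls:
            t = tallies.setdefault(call.chrom, {"WW": 0, "WC": 0, "CC": 0})
            if call.informative and call.state in t:
                t[call.state] += 1
    rows = []
    pvals = []
    tested = []
    exp = np.asarray(expected, dtype=float)
    exp = exp / exp.sum()
    for chrom, t in tallies.items():
        n = t["WW"] + t["WC"] + t["CC"]
        row = {"chrom": chrom, "n_WW": t["WW"], "n_WC": t["WC"], "n_CC": t["CC"],
               "n_informative": n}
        if n == 0:
            row.update({"freq_WW": np.nan, "freq_WC": np.nan, "freq_CC": np.nan,
                        "p_raw": np.nan})
        else:
            row.update({"freq_WW": t["WW"] / n, "freq_WC": t["WC"] / n,
                        "freq_CC": t["CC"] / n})
            chi2, p = stats.chisquare(
                [t["WW"], t["WC"], t["CC"]], f_exp=exp * n)
            row["chi2"] = float(chi2)
            row["p_raw"] = float(p)
            pvals.append(float(p))
            tested.append(chrom)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("chrom")
    df["p_holm"] = np.nan
    if pvals:
        df.loc[tested, "p_holm"] = multipletests(np.asarray(pvals),
                                                 method="holm")[1]
    return df.reset_index()
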