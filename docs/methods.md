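# Methods

## The measurement model

A Strand-seq library sequences only the parental template strands of one
cell.  Under random chromatid segregation each diploid chromosome inherits
WW, WC or CC templates with probability 1/4, 1/2, 1/4; haploid (sex)
chromosomes inherit a single W or C template with probability 1/2.  Reads
aligning to the plus strand report a Crick template, minus-strand reads a
Watson template.  Three signal classes sit on top of this:

- an SCE on one chromatid flips that homologue's template downstream of
  the breakpoint, so the chromosome switches between a homozygous and a
  heterozygous state at one position *in one cell*;
- a misoriented reference segment flips the apparent strand of every read
  inside it, producing a WW↔CC (or, on haploid chromosomes, W↔C) switch at
  the same position *in every cell*;
- background — spurious reads on the non-template strand, from incomplete
  BrdU-strand removal — relabels a fraction of reads uniformly.

All coordinates are 0-based half-open internally; BED output is native,
and only human-readable reports use 1-based positions.

## State calling and library quality

The chromosome-wide ratio r = (W − C)/(W + C) is rounded to the nearest of
{−1, 0, 1} → CC/WC/WW (ties at |r| = 0.5 round away from zero, so an
exactly half-skewed chromosome is called homozygous; this convention is
covered by a test).  Calls need at least `min_reads` (default 20) reads; what counts as
"sufficient reads" is a judgment call, so the threshold is configurable.
Copy-number-1 chromosomes are called W or C by majority strand.

Background is pooled (read-weighted) over a library's homozygous
chromosomes: b = 100 × (opposite-strand reads) / (all reads on those
chromosomes).  Pooling is more stable than a per-chromosome average when
chromosomes are short; the alternative reading of "average frequency" is
noted as an open choice.  Libraries with no homozygous chromosome get an
undefined-background flag rather than being dropped.

Ploidy: relative depth d = chromosome mean per-bin depth / library mean
per-bin depth, copy number n = round(2d) with halves away from zero
(d = 0.5 → monosome, d = 1.5 → triploid).  Segregation across libraries is
tested per chromosome with a chi-square goodness-of-fit against 1:2:1 (the
null that follows from random segregation; overridable) and Holm-adjusted
across chromosomes via `statsmodels`.

## Bin filtering

Bins of unexpected depth (collapsed repeats, unannotated gaps) corrupt the
ratio track, so bins are masked before segmentation.  A bin is masked when
its total count deviates from the **median of its own chromosome's
non-empty bins** by more than `max(t × SD, 3 × sqrt(median))`, with
`t = 0.2` by default and SD the library-wide spread of bin totals around
their chromosome medians.  Two deliberate choices here:

- the center is per-chromosome, because a monosomic chromosome sits at
  half the library depth *legitimately* — a library-wide center would mask
  it wholesale and blind the haploid analyses;
- the `3·sqrt(median)` floor keeps ordinary counting noise unmasked.  The
  SD term is meaningful on real, overdispersed libraries where the spread
  is dominated by aberrant bins; on clean (near-Poisson) data a bare
  `0.2 × SD` band would mask the great majority of bins and destroy the
  two-bin localization geometry, which is not a tenable reading of the
  filter's purpose.

`t = ∞` disables masking entirely.

## Segmentation (CBS)

Changepoints in the per-bin ratio are found with circular binary
segmentation, implemented here directly: for a segment, the arc (i, j)
maximizing the arc-vs-complement mean-shift statistic is tested by
permutation (α = 0.01, 1,000 permutations, seeded RNG) and accepted splits
recurse.  Numerical choices:

- the permutation p-value counts **strict** exceedances.  The ratio track
  of a clean library is a discrete two-level signal, and any permutation
  that merely re-creates a contiguous arrangement ties with the observed
  maximum; counting ties against the split would make clean, obvious
  changepoints non-significant.  Constant segments are never split, and
  spurious splits within one level vanish in the rounding merge below;
- arcs (and the edge pieces their cuts create) must span at least 2 bins.
  Isolating a single bin is permutation-invariant — every permutation
  attains the same statistic — which degenerates the test, and a one-bin
  feature is below the method's resolution regardless (two SCEs closer
  than one bin on the same chromosome are not detectable at the gross
  pass; planted-pair simulations confirm this as the dominant residual
  miss mode);
- segment means are rounded to {−1, 0, 1} and equal-level neighbours
  merged, enforcing that only WW/WC/CC calls exist.  Changepoints are
  reported as the two-bin interval spanning the last bin of one level run
  and the first bin of the next, in true coordinates (spanning any masked
  bins between them).

The same backend segments the relative-depth track for CNV calling, with
segment copy = round(2 × relative depth) and equal-copy neighbours merged.

## Iterative refinement and the walker

Each two-bin interval is refined iteratively: pad by half the interval
width per side (clipped to the chromosome), re-bin the padded region at
one fifth of the current interval width (80 kb on the first iteration for
a 400 kb interval), re-segment, and keep the new two-bin interval.
Iteration stops when the interval holds fewer than 50 reads, when
re-segmentation does not find exactly one changepoint, or when the
candidate interval would not shrink.  The trace of accepted intervals is
kept and reported.

The walker then scans reads from the homozygous flank and accepts the
first opposite-template read whose 10 preceding reads (in scan order) all
carry the homozygous template and whose window of 20 reads from the
candidate onward contains at least 4 opposite-template reads (at the end
of data the window requirement scales as 20% of the remaining reads,
minimum 1).  The candidate itself counts toward the 4.  Reads flanking the
refined interval are provided to the walker as context for these checks
but are not themselves eligible candidates.  The reported interval is the
gap between the accepted read and its predecessor — a between-two-reads
localization.

Classification: homozygous↔heterozygous = SCE; WW↔CC = misorientation
candidate; any switch on a copy-number-1 chromosome = haploid switch
(an SCE and a misorientation are indistinguishable per cell there).
Chromosomes with copy number above 2 are skipped with a warning; events
whose gross interval touches a chromosome end are flagged terminal.

### Localization accuracy and read density

The walker's forward window spans ≈ 20/ρ kb at read density ρ reads/kb,
and a background read up to ≈ (20 − 8)/ρ kb before the true boundary can
be accepted once the window reaches the heterozygous region.  Localization
to within 10 kb is therefore only coherent when the window itself spans
≲ 10 kb, i.e. ρ ≥ 2 reads/kb.  The simulation study conditions use
ρ = 2 reads/kb (a well-sequenced library; at ≈ 1 read/kb the same rule
leaves ~10–15% of events localized 10–20 kb off — an inherent property
of the windowed acceptance rule, not of this implementation).  At background
0 the walker interval is exactly the gap between the first
opposite-template read and its predecessor, which the tests verify
read-for-read against the simulator's truth.

## Cross-library integration

Events recur by single-linkage clustering on ≥ 1 bp interval overlap
(threshold configurable); clusters of ≥ 2 events are reported with the
intersected interval, occurrence count and contributing libraries —
recurrent SCE regions and genuine rearrangements are *not* auto-separated,
matching the method's scope.  Misorientation candidates are clustered the
same way and paired left-to-right into segments (entry and exit boundary;
an unpaired boundary extends to the chromosome end).  Concordance divides
by the libraries **able to show the flip**: homozygously inherited
libraries for diploid WW↔CC segments (a WC chromosome is blind to
misorientation), all informative libraries on haploid chromosomes, where
boundary clusters must additionally recur in every informative library to
be distinguished from ordinary SCEs.

## Scaffold placement

Chromosomes are split at the pooled SCE midpoints of all libraries (the
finest grid on which every library's state is constant) and each region's
state is called per library.  A scaffold's per-library states are scored
against every region: heterozygous matches confirm co-location but are
orientation-neutral; homozygous matches vote same-orientation when equal
and reverse when mirrored.  Concordance = 100 × matches / mutually
informative libraries; the best region places the scaffold (ties across
regions → ambiguous), orientation is the majority of same vs reverse
votes, and a placement is confident with > 10 informative libraries and
> 60% concordance (the standard operating thresholds for this analysis; the margin
between clearly failing and clearly passing placements is narrow, so
both are configurable).  Scaffolds
that are never heterozygous across ≥ 5 informative libraries (< 5%
probability for a diploid fragment) are scored only against haploid
chromosomes.

Gap cross-referencing keeps gaps overlapping the best region; a gap
qualifies if unbridged (unknown size) or bridged with length ≥ the
scaffold; qualifying gaps rank unbridged-first by size, the top one
becoming the primary candidate.  The FASTA rewriter reverse-complements
misoriented intervals in place and writes each placed scaffold
(reverse-complemented when placed in reverse) into the center of its
primary gap, preserving flanking Ns when the gap is larger and replacing
the gap entirely (with a ledger note) when an unbridged gap is smaller
than the scaffold.  Edited records get a version suffix; coordinates of
downstream features are *not* lifted — the edit ledger is the only
record of the shifts.

## Early-build assembly

All-WC libraries (failed strand removal) and all-WC contigs (degenerate
sequence) are excluded first; contigs under 10 kb are dropped when lengths
are known.  Clustering is greedy and deterministic: contigs in descending
informative-library count (ties by name) join the existing group with the
highest all-states concordance to the group consensus (per-library
majority state of members, ties → uninformative) when it reaches the 0.85
threshold, else found a new group.  Orientation uses homozygous-only
concordance — mirrored groups score near 0 — and a greedy pass inverts
whichever group's inversion most increases the summed pairwise
homozygous-only concordance, stopping when no inversion helps (a group is
never inverted twice in a row; iteration capped).  Groups whose consensus
profiles then agree at the clustering threshold are merged.  Whether the
0.85 threshold should apply to all-states or homozygous-only concordance
is not fully determined by the source description; this package uses
all-states for clustering/merging and homozygous-only for orientation,
both configurable.

Within a group, distance = fraction of mutually informative libraries
with differing (orientation-corrected) state; undefined pairs get the
maximum distance 1.0 with a warning.  The shortest Hamiltonian path is
approximated by best-of-all-starts nearest neighbour plus 2-opt, with the
input order included as a candidate so the result never loses to it; for
groups of ≤ 8 contigs the heuristic provably matches brute force in the
test suite.  Groups with identical states everywhere are returned in
input order, flagged unordered — with no SCE between contigs their order
is genuinely undetermined.

Haploid-behaving contigs (never WC over ≥ 5 informative libraries, and
near-half depth when depth is supplied) are routed to a separate
clustering on W/C states.

## The simulator and what it does not emulate

`SimConfig` fixes the study conditions: chromosome lengths, number of
libraries (default 62), mean reads per library, background rate (default
0.03 — a mid-grade library; sub-1% is excellent, above 10% poor), SCE
specification (explicit positions or a Poisson rate per chromosome per
library), haploid chromosomes, misoriented segments, CNV regions,
scaffold extractions, ploidy overrides, and a seed; a fixed seed makes
every output byte-identical.  Reads are uniform 50 bp point intervals:
there is no coverage waviness, no mappability structure, no duplicate or
chimeric reads, no variable read length, and SCEs are planted on one
homologue only (so diploid transitions are homozygous↔heterozygous, with
WW↔CC reserved for misorientation planting); reciprocal SCEs in paired
daughter cells are not modelled.  Passing tests therefore demonstrate
correctness of the algorithms under the stated noise model, not
robustness to alignment artifacts of real libraries.

Problem sizes used by the test suite: recovery/localization runs use 60
libraries on three 30 Mb chromosomes at 2 reads/kb with two planted SCEs
per chromosome per library; scaffold-placement trials use 100 seeded
repetitions of 60 libraries on two 8 Mb chromosomes at 3% background;
assembly runs use two 24 Mb chromosomes split into 10 fragments each, 60
libraries, SCE rate 0.2 per chromosome per library (about 12 informative
breakpoints per chromosome pooled across libraries, enough to order ten
fragments; at rates ≳ 1 the same pipeline legitimately fragments chromosomes
into several linkage groups, as distant contigs genuinely decorrelate).

## Known limitations

- Two SCEs closer than one bin (or than the walker window) on the same
  chromosome merge or vanish; terminal events are flagged but intervals
  clipped at chromosome ends remain harder to localize.
- Detection is not attempted on chromosomes with more than two copies.
- Recurrent events are counted, not classified into
  translocation/inversion/deletion.
- The misorientation/SCE separation on haploid chromosomes requires full
  recurrence across informative libraries; with few libraries a recurrent
  SCE hotspot could mimic it.
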