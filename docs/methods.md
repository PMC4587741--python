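# Methods

## Data model and coordinate conventions

Map positions (BNX, CMAP, XMAP) are floating bp values measured from the
map start, as in the native formats; files are written with one decimal,
and the simulator rounds generated positions to one decimal so that a
write → read round trip is exact. AGP coordinates are 1-based inclusive.
Negative-strand XMAP records keep the on-disk convention (query start >
query end) in memory; interval arithmetic goes through `qry_lo`/`qry_hi`
accessors, giving a single code path without a lossy normalization step.
Each CMAP record carries its channel-0 end marker only on disk; in memory
`sites` holds real labels and `num_sites` is derived, which makes the
"NumSites disagrees with rows" corruption detectable on read.

## In silico digestion

A label site is the 1-based leftmost base of a motif match on the forward
strand, merging forward and reverse-complement occurrences (a palindromic
motif is counted once). The leftmost-base convention, rather than the
enzyme's nick offset, is a deliberate choice: label-interval geometry is
invariant to a constant shift, so nothing downstream can distinguish the
two, and the leftmost base needs no per-enzyme offset table. Defaults are
the two 7 bp nicking motifs `GCTCTTC` (nt.BspQI) and `CCTCAGC` (nt.BbvCI)
merged onto one label channel, matching dual-nicking single-colour
labelling; per-enzyme channels are available for density reporting.

A scaffold qualifies for an *in silico* map only if it is **longer than**
20 kb with **more than** 5 labels (strict minima). Label density is
`1e5 · sites / length`; the ideal band is treated as the closed interval
[10, 15] since no exclusivity is specified anywhere for it.

## Molecule stretch (bpp) correction

Imaging nominally resolves 500 bases per pixel; per-scan drift is
corrected against the sequence, which is treated as the more accurate
length standard. The per-scan estimator is the ratio of summed aligned
spans, `scale = Σ ref_span / Σ qry_span` (a length-weighted mean), rather
than a per-molecule mean: short noisy alignments then contribute in
proportion to their length. `bpp = 500 · scale`; scans outside the
configurable QC band [475, 525] (±5 %) are flagged, as is any scan with no
alignments (which is left unscaled). Rescaling multiplies positions and
lengths by `scale`, so re-estimation on consistently rescaled data returns
a scale of 1 to numerical precision (asserted at 1e-9). The minimum
molecule length filter is inclusive (`length ≥ threshold`); results differ
from a strict reading only for molecules exactly at the boundary.

## Assembly sweep

The p-value threshold triple is derived from the estimated genome length
`G` in Mb: `default = numerator / G`, `strict = default/10`,
`relaxed = default·10`. The numerator defaults to **1e-6**, the value that
reproduces the canonical triple (5e-09 default, 5e-10 strict, 5e-08
relaxed) at `G = 200`; it is an explicit config field because reasonable
alternative calibrations exist. Staging is: three threshold runs at the
150 kb default minimum molecule length, then (if needed) the best
threshold at 100 kb and 180 kb — between three and nine distinct configs.
Run configs are emitted as declarative YAML; invoking the external
assembler is the user's step.

Candidate assemblies are scored on two ideals — cumulative map length
equal to the haploid genome length, and non-redundant alignment to the
*in silico* maps — and ranked lexicographically by (redundancy/breadth,
|cumulative − G|/G). Redundancy-first is the default ordering; a
length-first ordering is available because the two ideals carry no
inherent precedence, and the full table is always reported so a human can
override. Zero-breadth candidates rank last (infinite redundancy ratio).

## Stitch

**PAT.** "Alignment length" is measured as the aligned span on the
consensus map (the reference after inversion): the consensus map is the
scaffolding coordinate system, and the original tool's choice among
ref-span, query-span or label count is not documented anywhere we could
follow. Total possible length adds, on each side, the smaller of the
reference and query overhangs, with query overhangs swapped for `-`
alignments. All threshold comparisons (confidence, PAT, the 60 % partial
boundary, the −20 kb gap boundary) are inclusive on ≥ and strict on <, and
the CLI help states this.

**Selection.** Scaffolding candidates are restricted to consensus maps
with ≥ 2 distinct aligned *in silico* maps *before* the per-map best is
chosen; this ordering is what lets a later iteration use an alignment
whose better-scoring rival sits on a consensus map that can no longer
produce a join. "Chosen arbitrarily" on full ties is implemented as the
smallest (consensus id, entry id) — deterministic across runs.

**Gaps and building.** Projection assumes 1 bp of scaffold ≙ 1 bp of
consensus map, valid after stretch normalization; overhangs are not
rescaled per alignment. Positive gaps are rounded to the nearest bp (min
1) and written as `N` gaps with linkage `yes`, evidence `map`; negative
*and zero* gaps get the fixed 100 bp `U` spacer, since a zero-length run
of N would silently fuse two scaffolds into one contig. By default
extreme negative gaps (< −20 kb) are only flagged, matching the behaviour
used for the published genome update; the minimum-negative-gap *exclusion*
(both flanking maps dropped from joining for the iteration) is opt-in,
matching the later software revision.

## Iteration and AGP flattening

The sewing machine re-digests the stitched FASTA each round, re-aligns via
a pluggable aligner (`aligner(ref_maps, qry_maps, context)`; the context
carries the digestion key, the object → original-component registry and
the iteration number), inverts, and stitches; it stops at `n_new_joins =
0` or `max_iter` (default 5, overridable). The super-scaffold counter is
global across iterations so names are never reused. Only the AGP of
objects *created* in a pass is accumulated; flattening resolves nested
objects recursively with orientation composition (− ∘ − = +), recomputes
coordinates, preserves gap lines, and raises on registry cycles. Across
iterations the record count is non-increasing, N50 non-decreasing, and
the non-N base content constant (joins add only N).

## The simulator

The generator emulates: an i.i.d. random genome at a chosen GC fraction
(default 0.45, giving ≈ 19 labels/100 kb for the two default motifs —
near the ideal band); a draft assembly as scaffolds separated by true gaps
of 0–5 kb, shuffled and with ~40 % reverse-complemented so order *and*
orientation must be recovered; consensus genome maps with multiplicative
sizing noise on label intervals, binomial label dropout, and Poisson false
labels; and BNX molecules carrying per-scan stretch factors.

The default dataset is 5 Mb in **10 chromosomes** with 40 scaffolds and
one consensus map contig per chromosome. Chromosome-scale map contigs are
the geometry in which map super-scaffolding is informative (the real use
case orders scaffolds within chromosome linkage groups). An overlapping
tiling of many short maps was evaluated and rejected as a default: under
the one-alignment-per-in-silico-map rule, each pass can only join a
matching on the chain of map-boundary junctions, so full recovery would
need ~log₂(k) iterations and no parameter setting fixes that — it is a
property of the joint geometry, not of the implementation. A dedicated
bridge fixture (two overlapping maps, three scaffolds) exercises the
genuine second-iteration join, where a merged super-scaffold's alignment
becomes usable only after its best-scoring consensus map stops being a
join candidate.

Two stand-in aligners replace the external (non-redistributable) aligner:
a provenance-based truth aligner with idealized coordinates, and a naive
label-offset overlap aligner (anchor offsets from the first few labels of
either map, greedy two-pointer pairing within a tolerance, best offset
wins, both orientations tried). For both, the confidence proxy is the
**matched-label count**, not a −log10 p-value; simulated runs therefore
scale confidence thresholds to label counts (the test suite uses
(6, 30)/(4, 90) against the published (13, 30)/(8, 90) PAT values, which
are unit-free and kept as-is).

**What passing tests do not show:** the simulator has no fragile-site
breakage, no chimeric scaffolds, no structural disagreement between
sequence and maps, and its noise is independent across labels; recovery
rates here therefore bound the easy part of the problem (geometry,
orientation algebra, gap inference, iteration) and say nothing about
alignment quality on real data, which is the external aligner's job.
Adjacency recovery is measured over scaffolds *eligible* for an in silico
map: a scaffold below the 20 kb / 5-label minimum has no map and cannot be
placed by any aligner, so consecutive eligible scaffolds (per chromosome)
form the denominator.

## Problem sizes and runtime

Defaults were sized for interactive use: the 5 Mb / 40-scaffold datasets
drive the recovery tests, a 2 Mb / 16-scaffold variant carries the
molecule/stretch tests, and the whole suite runs in well under a minute on
one CPU. The naive aligner is quadratic in label count per map pair and is
meant for desk-scale maps only.

## Known limitations

No sequence-level local assembly across negative gaps; no automatic
breaking of chimeric scaffolds (flags point a curator at them); genetic
maps are not consumed; BNX quality rows are preserved verbatim but not
interpreted; the assembler/aligner noise parameters are passed through,
never estimated.
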