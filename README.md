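# stitchkit

Toolkit for super-scaffolding draft genome assemblies with optical genome
maps. It covers the map-side workflow around a (proprietary, external) map
assembler and aligner: preparing single-molecule map data (BNX), digesting
sequence scaffolds into *in silico* maps (CMAP), planning and ranking map
assemblies, and — its core — the **Stitch** algorithm, which turns
consensus-map-to-*in silico*-map alignments (XMAP) into ordered, oriented
super-scaffolds with estimated gaps, emitted as FASTA + AGP 2.0. The
**sewing machine** driver iterates digest → align → stitch until no new
super-scaffolds appear.

It is written for genome-finishing practitioners with a fragmented draft
assembly and Bionano-style single-molecule map data, and for anyone who
needs honest, testable plumbing for the BNX / CMAP / XMAP text formats.

## The method

An external aligner aligns consensus genome maps (query) to *in silico*
maps (reference) and reports, per alignment, spans on both maps, an
orientation, and a confidence score `c = -log10(p_FP)`. Stitch inverts the
alignment so the consensus map becomes the scaffolding coordinate system,
then:

1. **Filter.** Besides the confidence threshold, local alignments are
   removed with the *percent aligned threshold* (PAT). With aligned
   reference span `a`, reference overhangs `r_l, r_r` and query overhangs
   `q_l, q_r` (taken in alignment orientation),

   ```
   PAT = 100 · a / (a + min(r_l, q_l) + min(r_r, q_r))
   ```

   so a true overlap or containment scores 100 and an interior local hit
   scores low. Two filter sets are applied and an alignment passing either
   is kept — by default `(c ≥ 13, PAT ≥ 30)` and `(c ≥ 8, PAT ≥ 90)`.
2. **Select.** Only consensus maps with ≥ 2 aligned *in silico* maps can
   scaffold; each *in silico* map contributes its single longest alignment
   (ties: highest confidence, then smallest map id — deterministic).
3. **Join.** Scaffolds are ordered by their projected interval on the
   consensus map (aligned span extended by the unaligned scaffold
   overhangs); the signed gap between neighbours is the projection
   distance. Positive gaps become runs of `N` of the estimated size (AGP
   `N` line); negative or unknown gaps become a fixed 100 bp spacer (AGP
   `U` line).
4. **Flag.** Passing alignments with PAT < 60 % are reported as partial
   alignments and gaps < −20 kb as extreme negative gaps — both point at
   possible chimeric or mis-assembled sequence. Optionally, both flanks of
   a sub-threshold negative gap are excluded from joining.

Up front, the assembly sweep planner derives the p-value threshold triple
from the estimated genome length `G` (Mb): `T_default = 1e-6 / G`,
`T_strict = T_default / 10`, `T_relaxed = T_default × 10` (for a 200 Mb
genome: 5e-09, 5e-10, 5e-08), stages three threshold runs at a 150 kb
minimum molecule length and then two minimum-length variants (100 and
180 kb), and ranks candidate assemblies by alignment redundancy and
closeness to the estimated genome length.

Because the external assembler/aligner is not redistributable, the
`simulate` module generates complete synthetic datasets with ground truth
(fragmented genomes, noisy consensus maps, stretched molecules) and two
clearly-labelled stand-in aligners, so every stage is testable offline.

## Worked example

Simulate a 2 Mb genome fragmented into 16 scaffolds, then stitch it back
together from the truth alignments:

```
$ stitchkit simulate --length 2000000 --scaffolds 16 --seed 17 --out-dir sim
wrote dataset to sim (16 scaffolds, 10 consensus maps, 16 truth alignments)

$ stitchkit digest --fasta sim/scaffolds.fa --out insilico.cmap --key key.txt
16 maps written; 0 scaffolds excluded; label density 18.08/100kb (outside the ideal 10-15 band)

$ stitchkit stitch --fasta sim/scaffolds.fa --xmap sim/truth.xmap \
      --key sim/insilico_key.txt --f1 6,30 --f2 4,90 --out-prefix run1
6 joins; 0 flags; 10 records written
```

The digest step reports how many scaffolds qualified for an *in silico*
map (here all 16; >20 kb with >5 labels) and the label density per 100 kb
(18.08 — above the ideal 10–15 band, meaning labels are denser than a real
nicking run would aim for). The stitch pass makes 6 joins, reducing 16
scaffolds to 10 records; `run1.fasta`, `run1.agp`, `run1.joins.log` and
`run1.flags.log` hold the super-scaffolds, their AGP description and the
join/flag evidence. Note the `--f1/--f2` confidence values are scaled down
here because the simulator's confidence proxy is a matched-label count,
not an external aligner's `-log10 p`.

The iterative driver (with the built-in naive overlap aligner) runs the
loop to its fixpoint and prints the contiguity trajectory:

```
$ stitchkit sewing-machine --fasta sim/scaffolds.fa --cmap sim/consensus.cmap \
      --f1 6,30 --f2 4,90 --out-dir sew
 iteration  n_records      n50  total_length  n_new_joins
         1          8 274926.0     1986963.0            8
         2          7 405117.0     1987063.0            1
         3          6 405117.0     1987163.0            1
         4          6 405117.0     1987163.0            0
```

Record count falls and N50 rises monotonically; iterations 2 and 3 find
joins that only become possible once earlier super-scaffolds exist, and
the run stops when a pass adds nothing new.

Assembly sweep planning is a one-liner:

```
$ stitchkit sweep-plan --genome-mb 200 --out-dir plans
plans/relaxed_t.yaml: T=5.0e-08 minlen=150000
plans/default_t.yaml: T=5.0e-09 minlen=150000
plans/strict_t.yaml: T=5.0e-10 minlen=150000
```

## Layout

| module | role |
| --- | --- |
| `stitchkit.formats` | BNX / CMAP / XMAP / FASTA / AGP / key-file IO and the data model |
| `stitchkit.digest` | *in silico* digestion, inclusion rules, label density |
| `stitchkit.prep` | per-scan stretch (bpp) estimation, rescaling, QC, merge |
| `stitchkit.stats` | N50 / cumulative-length and alignment-coverage summaries |
| `stitchkit.sweep` | threshold triple, sweep staging, assembly ranking |
| `stitchkit.stitch` | one Stitch pass: filter → select → join → flag → build |
| `stitchkit.pipeline` | sewing-machine iteration and AGP flattening |
| `stitchkit.simulate` | synthetic data with ground truth; stand-in aligners |
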