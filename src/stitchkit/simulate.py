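"""Synthetic optical-mapping data with exact ground truth.

Generates everything the pipeline consumes with no downloads and no
proprietary tools: a random genome, a fragmented scaffold FASTA (shuffled,
with a random subset reverse-complemented so order *and* orientation must
be recovered), consensus genome maps with realistic noise (multiplicative
sizing error on label intervals, label dropout, Poisson false labels),
BNX molecules carrying per-scan stretch factors, and alignments.

Two stand-in aligners are provided because the real aligner is external:

* :class:`TruthAligner` / :func:`truth_xmap` — provenance-based synthetic
  alignments with idealized coordinates; the confidence proxy is the
  matched-label count, NOT the external aligner's −log10 p-value, so tests
  exercising confidence thresholds scale them accordingly.
* :func:`naive_overlap_align` — an exhaustive label-offset overlap aligner
  for desk-scale demos and tests.

Default simulation scale (5 Mb, 40 scaffolds) runs the full pipeline in
seconds.  All generators are reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .digest import DigestConfig, digest_fasta, find_label_sites
from .formats import (
    CmapSite,
    ConsensusMap,
    KeyRow,
    MapAlignment,
    MoleculeMap,
    reverse_complement,
)

DEFAULT_MOTIFS = ("GCTCTTC", "CCTCAGC")


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldTruth:
    scaffold_id: str
    start: int            # genome interval [start, end), 0-based
    end: int
    orientation: str      # orientation of the stored FASTA sequence
    gap_after: int | None  # true gap to the next scaffold (genome order)
    chromosome: int = 0   # no scaffold spans a chromosome boundary

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ConsensusProvenance:
    cmap_id: int
    start: int            # genome interval [start, end) covered by the map
    end: int
    # retained true labels: (site index in the map, genome position, motif len)
    retained: list[tuple[int, int, int]] = field(default_factory=list)


@dataclass
class MoleculeTruth:
    molecule_id: int
    start: int
    end: int
    flowcell_id: str
    scan_id: int
    stretch: float


@dataclass
class SimulationTruth:
    """Everything needed to compute every expected downstream answer."""

    genome: str
    scaffolds: list[ScaffoldTruth]            # genome order
    chromosomes: list[tuple[int, int]] = field(default_factory=list)
    consensus: list[ConsensusProvenance] = field(default_factory=list)
    molecules: list[MoleculeTruth] = field(default_factory=list)
    stretch_factors: dict[tuple[str, int], float] = field(default_factory=dict)
    motifs: tuple[str, ...] = DEFAULT_MOTIFS

    def genome_sites(self) -> list[tuple[int, int]]:
        """All genome label sites as (1-based position, motif length)."""
        sites = []
        for motif in self.motifs:
            sites.extend((p, len(motif))
                         for p in find_label_sites(self.genome, motif))
        sites.sort()
        return sites


# ---------------------------------------------------------------------------
# genome and fragmentation
# ---------------------------------------------------------------------------


def make_genome(length: int, gc: float = 0.45, seed: int = 0) -> str:
    """Random i.i.d. genome with the given GC fraction."""
    if length <= 0:
        raise ValueError("length must be > 0")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = rng.choice(np.array(list("ACGT")), size=length, p=probs)
    return "".join(bases)


def split_chromosomes(genome_length: int,
                      n_chromosomes: int) -> list[tuple[int, int]]:
    """Equal-split chromosome intervals over [0, genome_length)."""
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    bounds = np.linspace(0, genome_length, n_chromosomes + 1).astype(int)
    return [(int(a), int(b)) for a, b in zip(bounds, bounds[1:])]


def fragment_genome(
    genome: str,
    n_scaffolds: int = 40,
    gap_low: int = 0,
    gap_high: int = 5000,
    revcomp_fraction: float = 0.4,
    seed: int = 0,
    chromosomes: Sequence[tuple[int, int]] | None = None,
) -> tuple[dict[str, str], list[ScaffoldTruth]]:
    """Cut the genome into scaffolds separated by gaps of random length
    (zero-length gaps allowed), reverse-complement a random subset, and
    shuffle the FASTA order.

    With ``chromosomes`` given, scaffolds are allocated to chromosome
    intervals proportionally to length and never span a boundary; true
    adjacencies then exist only within chromosomes.  The returned truth
    list stays in genome order; the FASTA dict is the shuffled presentation
    a scaffolder actually sees.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    if n_scaffolds < 1:
        raise ValueError("need at least one scaffold")
    if chromosomes is None:
        chromosomes = [(0, L)]
    # allocate scaffold counts proportionally to chromosome length
    chrom_lengths = np.array([e - s for s, e in chromosomes], dtype=float)
    counts = np.maximum(
        np.round(n_scaffolds * chrom_lengths / chrom_lengths.sum()), 1
    ).astype(int)
    while counts.sum() > n_scaffolds:
        counts[int(np.argmax(counts))] -= 1
    while counts.sum() < n_scaffolds:
        counts[int(np.argmin(counts))] += 1

    truth: list[ScaffoldTruth] = []
    sid = 1
    for chrom_idx, ((c_start, c_end), n_here) in enumerate(
            zip(chromosomes, counts)):
        n_here = int(n_here)
        c_len = c_end - c_start
        gaps = (rng.integers(gap_low, gap_high + 1, size=n_here - 1)
                if n_here > 1 else np.array([], dtype=int))
        seq_total = c_len - int(gaps.sum())
        if seq_total <= n_here:
            raise ValueError("gaps consume a whole chromosome")
        weights = rng.dirichlet(np.full(n_here, 30.0))
        lengths = np.maximum((weights * seq_total).astype(int), 1)
        lengths[-1] += seq_total - int(lengths.sum())
        pos = c_start
        for i in range(n_here):
            start, end = pos, pos + int(lengths[i])
            orientation = "-" if rng.random() < revcomp_fraction else "+"
            gap_after = int(gaps[i]) if i < n_here - 1 else None
            truth.append(ScaffoldTruth(f"scaffold_{sid}", start, end,
                                       orientation, gap_after, chrom_idx))
            sid += 1
            pos = end + (gap_after or 0)

    order = rng.permutation(len(truth))
    records: dict[str, str] = {}
    for idx in order:
        t = truth[idx]
        seq = genome[t.start:t.end]
        if t.orientation == "-":
            seq = reverse_complement(seq)
        records[t.scaffold_id] = seq
    return records, truth


# ---------------------------------------------------------------------------
# consensus maps and molecules
# ---------------------------------------------------------------------------


def tile_intervals(genome_length: int, map_length: int = 600_000,
                   overlap: int = 150_000) -> list[tuple[int, int]]:
    """Overlapping tiling of the genome used for consensus-map coverage."""
    if map_length <= overlap:
        raise ValueError("map_length must exceed overlap")
    intervals = []
    step = map_length - overlap
    start = 0
    while True:
        end = min(start + map_length, genome_length)
        intervals.append((start, end))
        if end >= genome_length:
            break
        start += step
    return intervals


def _noisy_map_from_interval(
    cmap_id: int,
    interval: tuple[int, int],
    genome_sites: Sequence[tuple[int, int]],
    sizing_sd: float,
    dropout: float,
    false_per_100kb: float,
    rng: np.random.Generator,
) -> tuple[ConsensusMap, ConsensusProvenance]:
    start, end = interval
    length = float(end - start)
    true_pos = [(g - start, g, m) for g, m in genome_sites
                if start < g <= end]
    # dropout
    kept = [(p, g, m) for p, g, m in true_pos if rng.random() >= dropout]
    # false labels
    n_false = rng.poisson(false_per_100kb * length / 1e5)
    false_pos = sorted(float(x) for x in rng.uniform(1.0, length, n_false))
    labels: list[tuple[float, int | None, int]] = (
        [(float(p), g, m) for p, g, m in kept]
        + [(p, None, 0) for p in false_pos])
    labels.sort()
    # multiplicative sizing noise on inter-label intervals
    noisy_positions: list[float] = []
    prov = ConsensusProvenance(cmap_id, start, end)
    prev_true, prev_noisy = 0.0, 0.0
    for pos, g, m in labels:
        interval_len = pos - prev_true
        factor = max(0.1, 1.0 + rng.normal(0.0, sizing_sd)) if sizing_sd else 1.0
        noisy = round(prev_noisy + interval_len * factor, 1)
        noisy_positions.append(noisy)
        prev_true, prev_noisy = pos, noisy
    tail = length - prev_true
    factor = max(0.1, 1.0 + rng.normal(0.0, sizing_sd)) if sizing_sd else 1.0
    map_length = round(prev_noisy + tail * factor, 1)
    sites = []
    for site_id, (noisy, (pos, g, m)) in enumerate(
            zip(noisy_positions, labels), start=1):
        sites.append(CmapSite(site_id, 1, noisy, coverage=10.0,
                              occurrence=10.0))
        if g is not None:
            prov.retained.append((site_id, g, m))
    cmap = ConsensusMap(cmap_id, max(map_length, 1.0), sites)
    return cmap, prov


def simulate_consensus_maps(
    genome: str,
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
    intervals: Sequence[tuple[int, int]] | None = None,
    map_length: int = 600_000,
    overlap: int = 150_000,
    sizing_sd: float = 0.0,
    dropout: float = 0.0,
    false_per_100kb: float = 0.0,
    seed: int = 0,
) -> tuple[list[ConsensusMap], list[ConsensusProvenance]]:
    """Consensus genome maps covering (overlapping) genome intervals, with
    sizing noise, label dropout and false labels.

    With zero noise each map's labels equal the digestion of the covered
    interval exactly.
    """
    rng = np.random.default_rng(seed)
    if intervals is None:
        intervals = tile_intervals(len(genome), map_length, overlap)
    genome_sites = []
    for motif in motifs:
        genome_sites.extend((p, len(motif))
                            for p in find_label_sites(genome, motif))
    genome_sites.sort()
    maps, provenance = [], []
    for i, interval in enumerate(intervals, start=1):
        cmap, prov = _noisy_map_from_interval(
            i, interval, genome_sites, sizing_sd, dropout,
            false_per_100kb, rng)
        maps.append(cmap)
        provenance.append(prov)
    return maps, provenance


def simulate_molecules(
    genome: str,
    scan_stretch: dict[tuple[str, int], float],
    n_per_scan: int = 60,
    mean_length: int = 220_000,
    min_length: int = 120_000,
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
    seed: int = 0,
) -> tuple[list[MoleculeMap], list[MoleculeTruth]]:
    """Single-molecule maps sampled from random genome intervals; each
    scan's molecules are stretched by the scan's factor (positions and
    lengths multiplied by it), emulating bpp drift."""
    rng = np.random.default_rng(seed)
    genome_sites = []
    for motif in motifs:
        genome_sites.extend(find_label_sites(genome, motif))
    genome_sites = np.array(sorted(genome_sites))
    molecules, truth = [], []
    mol_id = 1
    for (flowcell, scan), stretch in scan_stretch.items():
        for _ in range(n_per_scan):
            length = int(min_length + rng.exponential(
                max(mean_length - min_length, 1)))
            length = min(length, len(genome) - 1)
            start = int(rng.integers(0, len(genome) - length))
            end = start + length
            inside = genome_sites[(genome_sites > start)
                                  & (genome_sites <= end)]
            positions = [round(float(g - start) * stretch, 1) for g in inside]
            molecules.append(MoleculeMap(
                mol_id, round(length * stretch, 1), positions, scan, flowcell))
            truth.append(MoleculeTruth(mol_id, start, end, flowcell, scan,
                                       stretch))
            mol_id += 1
    return molecules, truth


# ---------------------------------------------------------------------------
# truth alignments
# ---------------------------------------------------------------------------


def _ref_position(g: int, motif_len: int, t: ScaffoldTruth) -> float:
    """Map a genome label (1-based leftmost base) into stored-scaffold
    coordinates, honouring the stored orientation."""
    local = g - t.start  # 1-based within the forward segment
    if t.orientation == "+":
        return float(local)
    return float(t.length - local - motif_len + 2)


def truth_xmap(
    consensus_provenance: Sequence[ConsensusProvenance],
    consensus_maps: Sequence[ConsensusMap],
    truth: SimulationTruth,
    key_rows: Sequence[KeyRow],
    min_matched: int = 2,
) -> list[MapAlignment]:
    """Exact alignments implied by provenance: in silico maps as reference,
    consensus maps as query, confidence = number of matched label pairs
    (a documented stand-in for the external aligner's score)."""
    by_header = {t.scaffold_id: t for t in truth.scaffolds}
    maps_by_id = {m.cmap_id: m for m in consensus_maps}
    out: list[MapAlignment] = []
    entry = 1
    for key in key_rows:
        t = by_header.get(key.header)
        if t is None:
            continue
        scaffold_digest = None
        for prov in consensus_provenance:
            ov_start = max(t.start, prov.start)
            ov_end = min(t.end, prov.end)
            if ov_end - ov_start <= 0:
                continue
            matched = [(site_id, g, m) for site_id, g, m in prov.retained
                       if ov_start < g <= ov_end]
            if len(matched) < min_matched:
                continue
            qry_map = maps_by_id[prov.cmap_id]
            # reference span in stored-scaffold coordinates
            if t.orientation == "+":
                ref_lo = float(ov_start - t.start)
                ref_hi = float(ov_end - t.start)
            else:
                ref_lo = float(t.length - (ov_end - t.start))
                ref_hi = float(t.length - (ov_start - t.start))
            ref_lo = max(ref_lo, 0.0)
            ref_hi = min(ref_hi, float(t.length))
            qry_lo = max(float(ov_start - prov.start), 0.0)
            qry_hi = min(float(ov_end - prov.start), qry_map.contig_length)
            if ref_hi - ref_lo <= 0 or qry_hi - qry_lo <= 0:
                continue
            # label pairs in the map's site numbering vs the scaffold's
            if scaffold_digest is None:
                scaffold_digest = {
                    round(_ref_position(g, m, t)): i
                    for i, (g, m) in enumerate(
                        ((g, m) for g, m in truth.genome_sites()
                         if t.start < g <= t.end), start=1)
                }
            pairs = []
            for site_id, g, m in matched:
                ref_site = scaffold_digest.get(round(_ref_position(g, m, t)))
                if ref_site is not None:
                    pairs.append((ref_site, site_id))
            out.append(MapAlignment.create(
                entry_id=entry,
                qry_id=prov.cmap_id,
                ref_id=key.cmap_id,
                qry_interval=(qry_lo, qry_hi),
                ref_interval=(ref_lo, ref_hi),
                orientation=t.orientation,
                confidence=float(len(matched)),
                qry_len=float(qry_map.contig_length),
                ref_len=float(key.length),
                label_pairs=pairs,
            ))
            entry += 1
    return out


def truth_molecule_xmap(
    molecules_truth: Sequence[MoleculeTruth],
    truth: SimulationTruth,
    key_rows: Sequence[KeyRow],
    min_overlap: int = 30_000,
) -> dict[tuple[str, int], list[MapAlignment]]:
    """Per-scan molecule-vs-in-silico-map alignments implied by provenance,
    for stretch estimation: reference spans are true bp, query spans carry
    the molecule's stretch factor."""
    by_header = {t.scaffold_id: t for t in truth.scaffolds}
    out: dict[tuple[str, int], list[MapAlignment]] = {}
    entry = 1
    for mt in molecules_truth:
        for key in key_rows:
            t = by_header.get(key.header)
            if t is None:
                continue
            ov_start = max(t.start, mt.start)
            ov_end = min(t.end, mt.end)
            if ov_end - ov_start < min_overlap:
                continue
            if t.orientation == "+":
                ref_lo = float(ov_start - t.start)
                ref_hi = float(ov_end - t.start)
            else:
                ref_lo = float(t.length - (ov_end - t.start))
                ref_hi = float(t.length - (ov_start - t.start))
            qry_lo = (ov_start - mt.start) * mt.stretch
            qry_hi = (ov_end - mt.start) * mt.stretch
            aln = MapAlignment.create(
                entry_id=entry,
                qry_id=mt.molecule_id,
                ref_id=key.cmap_id,
                qry_interval=(qry_lo, qry_hi),
                ref_interval=(ref_lo, ref_hi),
                orientation=t.orientation,
                confidence=10.0,
                qry_len=(mt.end - mt.start) * mt.stretch,
                ref_len=float(key.length),
            )
            out.setdefault((mt.flowcell_id, mt.scan_id), []).append(aln)
            entry += 1
    return out


class TruthAligner:
    """Provenance-based stand-in aligner for the iteration driver.

    Locates every current FASTA object on the genome through the flattened
    component registry (original scaffolds have known genome intervals) and
    emits the alignments a perfect overlap aligner would find, with
    idealized coordinates.  Confidence proxy = matched retained-label count.
    """

    def __init__(self, truth: SimulationTruth,
                 provenance: Sequence[ConsensusProvenance],
                 consensus_maps: Sequence[ConsensusMap],
                 min_matched: int = 4):
        self.truth = truth
        self.provenance = list(provenance)
        self.maps_by_id = {m.cmap_id: m for m in consensus_maps}
        self.min_matched = min_matched
        self.by_scaffold = {t.scaffold_id: t for t in truth.scaffolds}

    def _object_placement(
        self, components: list[tuple[str, str]]
    ) -> tuple[int, int, str, list[tuple[int, int]]] | None:
        """Genome interval, genome orientation, and covered sub-intervals of
        an object built from original components."""
        intervals = []
        parities = []
        for scaffold_id, placement in components:
            t = self.by_scaffold.get(scaffold_id)
            if t is None:
                return None
            intervals.append((t.start, t.end))
            genome_orient = ("+" if (t.orientation == "+") == (placement == "+")
                             else "-")
            parities.append(genome_orient)
        start = min(s for s, _ in intervals)
        end = max(e for _, e in intervals)
        orient = parities[0] if len(set(parities)) == 1 else "+"
        return start, end, orient, intervals

    def __call__(self, ref_maps: Sequence[ConsensusMap],
                 qry_maps: Sequence[ConsensusMap],
                 context: dict) -> list[MapAlignment]:
        key_rows: Sequence[KeyRow] = context["key"]
        registry: dict[str, list[tuple[str, str]]] = context.get(
            "components", {})
        out: list[MapAlignment] = []
        ref_lengths = {m.cmap_id: m.contig_length for m in ref_maps}
        entry = 1
        for key in key_rows:
            components = registry.get(key.header, [(key.header, "+")])
            placed = self._object_placement(components)
            if placed is None:
                continue
            obj_start, obj_end, obj_orient, covered = placed
            obj_len = ref_lengths[key.cmap_id]
            genome_span = obj_end - obj_start
            scale = obj_len / genome_span if genome_span > 0 else 1.0
            for prov in self.provenance:
                ov_start = max(obj_start, prov.start)
                ov_end = min(obj_end, prov.end)
                if ov_end - ov_start <= 0:
                    continue
                matched = sum(
                    1 for _, g, _ in prov.retained
                    if ov_start < g <= ov_end
                    and any(s < g <= e for s, e in covered))
                if matched < self.min_matched:
                    continue
                if obj_orient == "+":
                    ref_lo = (ov_start - obj_start) * scale
                    ref_hi = (ov_end - obj_start) * scale
                else:
                    ref_lo = obj_len - (ov_end - obj_start) * scale
                    ref_hi = obj_len - (ov_start - obj_start) * scale
                qry_map = self.maps_by_id[prov.cmap_id]
                qry_lo = max(float(ov_start - prov.start), 0.0)
                qry_hi = min(float(ov_end - prov.start),
                             qry_map.contig_length)
                ref_lo = max(ref_lo, 0.0)
                ref_hi = min(ref_hi, obj_len)
                if ref_hi - ref_lo <= 0 or qry_hi - qry_lo <= 0:
                    continue
                out.append(MapAlignment.create(
                    entry_id=entry,
                    qry_id=prov.cmap_id,
                    ref_id=key.cmap_id,
                    qry_interval=(qry_lo, qry_hi),
                    ref_interval=(ref_lo, ref_hi),
                    orientation=obj_orient,
                    confidence=float(matched),
                    qry_len=float(qry_map.contig_length),
                    ref_len=float(obj_len),
                ))
                entry += 1
        return out


# ---------------------------------------------------------------------------
# naive overlap aligner
# ---------------------------------------------------------------------------


def _count_matches(ref_pos: np.ndarray, shifted_qry: np.ndarray,
                   tol: float) -> int:
    """Greedy one-to-one pairing of two ascending position lists within a
    tolerance (two-pointer)."""
    i = j = matches = 0
    while i < len(ref_pos) and j < len(shifted_qry):
        d = shifted_qry[j] - ref_pos[i]
        if abs(d) <= tol:
            matches += 1
            i += 1
            j += 1
        elif d < 0:
            j += 1
        else:
            i += 1
    return matches


def naive_overlap_align(
    ref_map: ConsensusMap,
    qry_map: ConsensusMap,
    tolerance: float = 1000.0,
    min_matched: int = 4,
    n_anchors: int = 6,
) -> MapAlignment | None:
    """Exhaustive label-offset overlap alignment between two maps.

    Candidate offsets place the query on the reference so that an early
    label of one map coincides with some label of the other (an overlap must
    involve one map's end); labels are then paired greedily within the
    tolerance and the offset with the most pairs wins, tried in both
    orientations.  Desk-scale stand-in for the external aligner; confidence
    proxy = matched-label count.
    """
    if ref_map.num_sites < 2 or qry_map.num_sites < 2:
        return None
    ref_pos = np.array(ref_map.positions)
    best: tuple[int, float, str] | None = None
    for orientation in ("+", "-"):
        if orientation == "+":
            qry_pos = np.array(qry_map.positions)
        else:
            qry_pos = np.sort(qry_map.contig_length
                              - np.array(qry_map.positions))
        offsets: set[float] = set()
        for j in range(min(n_anchors, len(qry_pos))):
            offsets.update(ref_pos - qry_pos[j])
        for i in range(min(n_anchors, len(ref_pos))):
            offsets.update(ref_pos[i] - qry_pos)
        seen: list[float] = []
        for d in sorted(offsets):
            if seen and d - seen[-1] < tolerance / 4:
                continue
            seen.append(d)
            m = _count_matches(ref_pos, qry_pos + d, tolerance)
            if best is None or m > best[0]:
                best = (m, d, orientation)
    if best is None or best[0] < min_matched:
        return None
    matched, offset, orientation = best
    # geometric overlap implied by the winning offset
    ref_lo = max(0.0, offset)
    ref_hi = min(float(ref_map.contig_length),
                 offset + float(qry_map.contig_length))
    if ref_hi - ref_lo <= 0:
        return None
    if orientation == "+":
        qry_lo, qry_hi = ref_lo - offset, ref_hi - offset
    else:
        qry_lo = float(qry_map.contig_length) - (ref_hi - offset)
        qry_hi = float(qry_map.contig_length) - (ref_lo - offset)
    return MapAlignment.create(
        entry_id=1,
        qry_id=qry_map.cmap_id,
        ref_id=ref_map.cmap_id,
        qry_interval=(qry_lo, qry_hi),
        ref_interval=(ref_lo, ref_hi),
        orientation=orientation,
        confidence=float(matched),
        qry_len=float(qry_map.contig_length),
        ref_len=float(ref_map.contig_length),
    )


class NaiveAligner:
    """Aligner-protocol wrapper around :func:`naive_overlap_align`."""

    def __init__(self, tolerance: float = 1000.0, min_matched: int = 4):
        self.tolerance = tolerance
        self.min_matched = min_matched

    def __call__(self, ref_maps: Sequence[ConsensusMap],
                 qry_maps: Sequence[ConsensusMap],
                 context: dict) -> list[MapAlignment]:
        out = []
        entry = 1
        for ref in ref_maps:
            for qry in qry_maps:
                aln = naive_overlap_align(ref, qry, self.tolerance,
                                          self.min_matched)
                if aln is not None:
                    aln.entry_id = entry
                    entry += 1
                    out.append(aln)
        return out


# ---------------------------------------------------------------------------
# bundled dataset and recovery metric
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    truth: SimulationTruth
    scaffolds: dict[str, str]
    insilico_maps: list[ConsensusMap]
    key_rows: list[KeyRow]
    consensus_maps: list[ConsensusMap]
    provenance: list[ConsensusProvenance]
    molecules: list[MoleculeMap]


def simulate_dataset(
    genome_length: int = 5_000_000,
    n_scaffolds: int = 40,
    n_chromosomes: int = 10,
    gc: float = 0.45,
    sizing_sd: float = 0.0,
    dropout: float = 0.0,
    false_per_100kb: float = 0.0,
    scan_stretch: dict[tuple[str, int], float] | None = None,
    n_molecules_per_scan: int = 0,
    seed: int = 0,
    digest_config: DigestConfig | None = None,
) -> SimulatedDataset:
    """One call producing every input the pipeline needs, plus truth.

    The genome is organized into chromosomes; scaffolds fragment each
    chromosome and consensus genome maps correspond to chromosome-scale map
    contigs (one map per chromosome interval), the geometry in which map
    scaffolding is informative.
    """
    genome = make_genome(genome_length, gc, seed)
    chromosomes = split_chromosomes(genome_length, n_chromosomes)
    scaffolds, layout = fragment_genome(genome, n_scaffolds, seed=seed + 1,
                                        chromosomes=chromosomes)
    truth = SimulationTruth(genome, layout, chromosomes=chromosomes)
    insilico, key_rows, _ = digest_fasta(scaffolds, digest_config)
    consensus, provenance = simulate_consensus_maps(
        genome, truth.motifs, intervals=chromosomes,
        sizing_sd=sizing_sd, dropout=dropout,
        false_per_100kb=false_per_100kb, seed=seed + 2)
    truth.consensus = provenance
    molecules: list[MoleculeMap] = []
    if scan_stretch and n_molecules_per_scan:
        molecules, mol_truth = simulate_molecules(
            genome, scan_stretch, n_molecules_per_scan, seed=seed + 3)
        truth.molecules = mol_truth
        truth.stretch_factors = dict(scan_stretch)
    return SimulatedDataset(truth, scaffolds, insilico, key_rows,
                            consensus, provenance, molecules)


def adjacency_recovery(
    truth: SimulationTruth,
    components: dict[str, list[tuple[str, str]]],
    eligible_ids: set[str],
) -> tuple[int, int]:
    """(recovered, total) true adjacencies among map-eligible scaffolds.

    Truth adjacencies are consecutive eligible scaffolds in genome order.  A
    pair counts as recovered when the two scaffolds are adjacent in some
    output object and their composed orientations are consistent with the
    genome, reading the object either forward or reverse.
    """
    eligible_order = [t for t in truth.scaffolds
                      if t.scaffold_id in eligible_ids]
    truth_pairs = {(a.scaffold_id, b.scaffold_id)
                   for a, b in zip(eligible_order, eligible_order[1:])
                   if a.chromosome == b.chromosome}
    stored_orient = {t.scaffold_id: t.orientation for t in truth.scaffolds}
    recovered = set()
    for parts in components.values():
        # genome-frame parity of each placed component
        frame = [(sid, (stored_orient.get(sid, "+") == "+") == (o == "+"))
                 for sid, o in parts]
        for (sid_a, fwd_a), (sid_b, fwd_b) in zip(frame, frame[1:]):
            if fwd_a and fwd_b and (sid_a, sid_b) in truth_pairs:
                recovered.add((sid_a, sid_b))
            elif not fwd_a and not fwd_b and (sid_b, sid_a) in truth_pairs:
                recovered.add((sid_b, sid_a))
    return len(recovered), len(truth_pairs)
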