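"""Contiguity and alignment-coverage summaries for map sets.

Equivalents of the bnx_stats / cmap_stats / xmap_stats / BNGCompare helper
scripts: N50 and cumulative length for molecule and consensus map sets, and
breadth / total / percent-aligned coverage of an alignment set measured on
either side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .formats import ConsensusMap, MapAlignment, MoleculeMap
from .prep import filter_by_min_length

DEFAULT_LENGTH_FILTERS = (100_000.0, 150_000.0, 180_000.0)


@dataclass
class MapSetStats:
    n_maps: int
    cumulative_length: float
    n50: float


@dataclass
class AlignmentCoverage:
    breadth: float          # union of aligned intervals (non-redundant)
    total_aligned: float    # sum of aligned spans (with redundancy)
    percent_aligned: float  # 100 * breadth / total map length of that side

    @property
    def redundancy(self) -> float:
        return self.total_aligned - self.breadth


def n50(lengths: Iterable[float]) -> float:
    """Largest length L such that maps of length >= L hold at least half the
    cumulative length (sort descending, accumulate, first crossing)."""
    lengths = sorted(lengths, reverse=True)
    if not lengths:
        raise ValueError("n50 of an empty set is undefined")
    total = sum(lengths)
    acc = 0.0
    for length in lengths:
        acc += length
        if acc >= total / 2:
            return length
    return lengths[-1]  # unreachable


def _set_stats(lengths: Sequence[float]) -> MapSetStats:
    if not lengths:
        warnings.warn("empty map set: N50 reported as 0", stacklevel=3)
        return MapSetStats(0, 0.0, 0.0)
    return MapSetStats(len(lengths), float(sum(lengths)), float(n50(lengths)))


def bnx_stats(
    molecules: Sequence[MoleculeMap],
    min_length_filters: Sequence[float] = DEFAULT_LENGTH_FILTERS,
) -> pd.DataFrame:
    """One stats row (n maps, cumulative length, N50) per length filter."""
    rows = []
    for min_length in min_length_filters:
        kept = filter_by_min_length(molecules, min_length)
        s = _set_stats([m.length for m in kept])
        rows.append({
            "min_length": min_length,
            "n_maps": s.n_maps,
            "cumulative_length": s.cumulative_length,
            "n50": s.n50,
        })
    return pd.DataFrame(rows, columns=["min_length", "n_maps",
                                       "cumulative_length", "n50"])


def cmap_stats(maps: Sequence[ConsensusMap]) -> MapSetStats:
    return _set_stats([m.contig_length for m in maps])


def _interval_union(intervals: list[tuple[float, float]]) -> float:
    """Total length of a union of half-open intervals; touching intervals
    merge."""
    if not intervals:
        return 0.0
    intervals.sort()
    total = 0.0
    cur_lo, cur_hi = intervals[0]
    for lo, hi in intervals[1:]:
        if lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
    total += cur_hi - cur_lo
    return total


def xmap_stats(
    alignments: Sequence[MapAlignment],
    maps: Sequence[ConsensusMap],
    side: str = "reference",
) -> AlignmentCoverage:
    """Alignment coverage on one side of an XMAP.

    ``breadth`` is the union of aligned intervals per map on the chosen side;
    ``total_aligned`` keeps redundancy; ``percent_aligned`` divides breadth by
    the summed length of all maps of that side.
    """
    if side not in ("reference", "query"):
        raise ValueError("side must be 'reference' or 'query'")
    known = {m.cmap_id for m in maps}
    per_map: dict[int, list[tuple[float, float]]] = {}
    total_aligned = 0.0
    for a in alignments:
        if side == "reference":
            map_id, lo, hi = a.ref_id, a.ref_start, a.ref_end
        else:
            map_id, lo, hi = a.qry_id, a.qry_lo, a.qry_hi
        if map_id not in known:
            raise ValueError(f"alignment {a.entry_id} references unknown "
                             f"{side} map id {map_id}")
        per_map.setdefault(map_id, []).append((lo, hi))
        total_aligned += hi - lo
    breadth = sum(_interval_union(iv) for iv in per_map.values())
    denom = sum(m.contig_length for m in maps)
    percent = 100.0 * breadth / denom if denom > 0 else 0.0
    return AlignmentCoverage(breadth, total_aligned, percent)


def compare_summary(
    fasta_lengths: Sequence[float],
    insilico_maps: Sequence[ConsensusMap],
    consensus_maps: Sequence[ConsensusMap],
    alignments: Sequence[MapAlignment],
) -> pd.DataFrame:
    """BNGCompare-style joint report: contiguity stats for the sequence
    assembly, the in silico maps and the consensus maps, plus alignment
    coverage measured on both sides (reference = in silico maps)."""
    blocks: list[dict] = []

    def add(block: str, s: MapSetStats) -> None:
        blocks.append({
            "block": block, "n": s.n_maps,
            "cumulative_length": s.cumulative_length, "n50": s.n50,
            "breadth": None, "total_aligned": None, "percent_aligned": None,
        })

    add("sequence_fasta", _set_stats(list(fasta_lengths)))
    add("insilico_maps", cmap_stats(insilico_maps))
    add("consensus_maps", cmap_stats(consensus_maps))
    for side, maps in (("reference", insilico_maps), ("query", consensus_maps)):
        if alignments:
            cov = xmap_stats(alignments, maps, side=side)
        else:
            cov = AlignmentCoverage(0.0, 0.0, 0.0)
        blocks.append({
            "block": f"coverage_{side}", "n": len(alignments),
            "cumulative_length": None, "n50": None,
            "breadth": cov.breadth, "total_aligned": cov.total_aligned,
            "percent_aligned": cov.percent_aligned,
        })
    return pd.DataFrame(blocks, columns=[
        "block", "n", "cumulative_length", "n50", "breadth",
        "total_aligned", "percent_aligned"])
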