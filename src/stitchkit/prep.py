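"""Molecule preparation: per-scan stretch (bpp) estimation and rescaling.

Imaging nominally resolves 500 bases per pixel (bpp), but actual stretch
drifts from scan to scan.  Sequence scaffolds are taken as the more accurate
length standard: molecules are split by scan, aligned externally to the
*in silico* maps, and each scan's empirical bpp is estimated from those
alignments as ``500 × (Σ reference aligned span) / (Σ query aligned span)``
— a length-weighted average that is robust to short noisy alignments.
Label positions are then rescaled so every scan sits at 500 bpp, QC'd, and
the scans merged back into one molecule set.

This module never aligns; alignments arrive as XMAP records produced by an
external aligner or by the simulator's stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .formats import MapAlignment, MoleculeMap

NOMINAL_BPP = 500.0
DEFAULT_QC_BAND = (475.0, 525.0)  # ±5 % around nominal


@dataclass
class ScanStretchEstimate:
    flowcell_id: str
    scan_id: int
    bpp: float
    scale: float
    n_alignments: int
    flagged: bool
    estimated: bool = True


def split_by_scan(
    molecules: Iterable[MoleculeMap],
) -> dict[tuple[str, int], list[MoleculeMap]]:
    """Partition molecules by (flowcell, scan), preserving input order."""
    parts: dict[tuple[str, int], list[MoleculeMap]] = {}
    for m in molecules:
        parts.setdefault((m.flowcell_id, m.scan_id), []).append(m)
    return parts


def estimate_scan_bpp(
    alignments: Iterable[MapAlignment],
    flowcell_id: str = "1",
    scan_id: int = 1,
    qc_band: tuple[float, float] = DEFAULT_QC_BAND,
) -> ScanStretchEstimate:
    """Estimate one scan's stretch from its molecules' alignments.

    With no alignments the estimate is absent: scale 1, flagged, and the
    downstream rescale becomes a no-op.
    """
    alignments = list(alignments)
    if not alignments:
        return ScanStretchEstimate(flowcell_id, scan_id, NOMINAL_BPP, 1.0,
                                   0, flagged=True, estimated=False)
    ref_total = sum(a.ref_span for a in alignments)
    qry_total = sum(a.qry_span for a in alignments)
    if qry_total <= 0:
        raise ValueError("degenerate alignments: zero query span")
    scale = ref_total / qry_total
    bpp = NOMINAL_BPP * scale
    flagged = not (qc_band[0] <= bpp <= qc_band[1])
    return ScanStretchEstimate(flowcell_id, scan_id, bpp, scale,
                               len(alignments), flagged)


def rescale_scan(
    molecules: Iterable[MoleculeMap],
    estimate: ScanStretchEstimate,
) -> list[MoleculeMap]:
    """Multiply positions and lengths by the scan's estimated scale."""
    if estimate.scale <= 0:
        raise ValueError("non-positive scale")
    out = []
    for m in molecules:
        out.append(MoleculeMap(
            molecule_id=m.molecule_id,
            length=m.length * estimate.scale,
            label_positions=[p * estimate.scale for p in m.label_positions],
            scan_id=m.scan_id,
            flowcell_id=m.flowcell_id,
            extra_rows=list(m.extra_rows),
        ))
    return out


def merge_scans(
    partitions: Mapping[tuple[str, int], list[MoleculeMap]],
) -> tuple[list[MoleculeMap], dict[tuple[str, int, int], int]]:
    """Concatenate scan partitions with globally unique molecule ids.

    Colliding ids are renumbered; the returned mapping logs
    ``(flowcell, scan, old_id) -> new_id`` for every renumbered molecule.
    """
    merged: list[MoleculeMap] = []
    seen: set[int] = set()
    renumbered: dict[tuple[str, int, int], int] = {}
    next_id = 1
    for key, molecules in partitions.items():
        for m in molecules:
            new_id = m.molecule_id
            if new_id in seen:
                while next_id in seen:
                    next_id += 1
                new_id = next_id
                renumbered[(key[0], key[1], m.molecule_id)] = new_id
                m = MoleculeMap(new_id, m.length, list(m.label_positions),
                                m.scan_id, m.flowcell_id, list(m.extra_rows))
            seen.add(new_id)
            merged.append(m)
    return merged, renumbered


def qc_report(estimates: Iterable[ScanStretchEstimate]) -> pd.DataFrame:
    """One row per scan: flowcell, scan, bpp, scale, alignment count, flag.

    Deterministically ordered by (flowcell, scan).
    """
    rows = [
        {
            "flowcell": e.flowcell_id,
            "scan": e.scan_id,
            "bpp": e.bpp,
            "scale": e.scale,
            "n_alignments": e.n_alignments,
            "flagged": e.flagged,
        }
        for e in estimates
    ]
    df = pd.DataFrame(
        rows, columns=["flowcell", "scan", "bpp", "scale", "n_alignments",
                       "flagged"],
    )
    if len(df):
        df = df.sort_values(["flowcell", "scan"]).reset_index(drop=True)
    return df


def plot_qc(report: pd.DataFrame, path: str | Path) -> None:
    """bpp-vs-scan QC graph, one panel trace per flowcell."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for flowcell, grp in report.groupby("flowcell"):
        ax.plot(grp["scan"], grp["bpp"], marker="o", label=f"flowcell {flowcell}")
    ax.axhline(NOMINAL_BPP, color="grey", linestyle="--", linewidth=1)
    ax.axhspan(*DEFAULT_QC_BAND, color="grey", alpha=0.15)
    ax.set_xlabel("scan")
    ax.set_ylabel("bases per pixel")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def filter_by_min_length(
    molecules: Iterable[MoleculeMap], min_length: float
) -> list[MoleculeMap]:
    """Keep molecules with ``length >= min_length`` (inclusive boundary)."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    return [m for m in molecules if m.length >= min_length]
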