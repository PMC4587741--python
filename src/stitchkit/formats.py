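"""Readers and writers for the optical-mapping text formats.

The toolkit speaks five plain-text formats:

* **BNX 1.x** — one block per imaged single-molecule map (a ``0`` line with
  molecule metadata, a ``1`` line with label positions, optional quality
  rows which are preserved verbatim).
* **CMAP 0.1** — consensus maps, either consensus genome maps assembled from
  molecules or *in silico* maps digested from sequence; one row per label
  site plus a channel-0 end marker at the map length.
* **XMAP 0.2** — pairwise map alignments with spans on both maps, an
  orientation, and a confidence score (the aligner's −log10 false-positive
  p-value; this toolkit only ever consumes that number).
* **FASTA** — sequence scaffolds (via Biopython).
* **AGP 2.0** — how super-scaffold objects are built from component
  scaffolds and gaps.

Coordinates follow the native conventions: CMAP/XMAP positions are floating
bp values measured from the map start, AGP is 1-based inclusive.  Negative
strand XMAP records store ``qry_start > qry_end`` exactly as on disk; use
:attr:`MapAlignment.qry_lo` / :attr:`MapAlignment.qry_hi` for interval math.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """A format file violated the expected layout."""


class InvariantError(ValueError):
    """A record violated a data-model invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MoleculeMap:
    """One imaged DNA molecule: length plus ordered label positions (bp).

    ``extra_rows`` retains any quality rows (``QX11`` etc.) verbatim so that
    a read→write round trip is lossless for rows this toolkit does not
    interpret.
    """

    molecule_id: int
    length: float
    label_positions: list[float]
    scan_id: int = 1
    flowcell_id: str = "1"
    extra_rows: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.length <= 0:
            raise InvariantError(f"molecule {self.molecule_id}: length must be > 0")
        prev = 0.0
        for pos in self.label_positions:
            if pos <= prev:
                raise InvariantError(
                    f"molecule {self.molecule_id}: label positions must be "
                    f"strictly ascending and > 0 (saw {pos} after {prev})"
                )
            prev = pos
        if self.label_positions and self.label_positions[-1] > self.length:
            raise InvariantError(
                f"molecule {self.molecule_id}: label position "
                f"{self.label_positions[-1]} exceeds length {self.length}"
            )


@dataclass
class CmapSite:
    site_id: int
    channel: int
    position: float
    stddev: float = 0.0
    coverage: float = 1.0
    occurrence: float = 1.0


@dataclass
class ConsensusMap:
    """One CMAP record: a consensus genome map or an *in silico* map.

    ``sites`` holds the real label sites only; the channel-0 end marker at
    ``contig_length`` is synthesized on write and stripped on read.
    """

    cmap_id: int
    contig_length: float
    sites: list[CmapSite] = field(default_factory=list)

    @property
    def num_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> list[float]:
        return [s.position for s in self.sites]

    def validate(self) -> None:
        if self.contig_length <= 0:
            raise InvariantError(f"cmap {self.cmap_id}: length must be > 0")
        prev = 0.0
        for s in self.sites:
            if s.position < prev:
                raise InvariantError(
                    f"cmap {self.cmap_id}: site positions must be non-decreasing"
                )
            prev = s.position
        if self.sites and self.sites[-1].position > self.contig_length:
            raise InvariantError(
                f"cmap {self.cmap_id}: site beyond contig length"
            )


@dataclass
class MapAlignment:
    """One XMAP record.

    ``qry_start``/``qry_end`` follow the on-disk convention: for orientation
    ``-`` the stored query start is greater than the stored query end.  The
    confidence score is produced by the external aligner and only consumed
    here.
    """

    entry_id: int
    qry_id: int
    ref_id: int
    qry_start: float
    qry_end: float
    ref_start: float
    ref_end: float
    orientation: str
    confidence: float
    hit_enum: str = ""
    qry_len: float | None = None
    ref_len: float | None = None
    label_channel: str = "1"
    label_pairs: list[tuple[int, int]] = field(default_factory=list)

    @classmethod
    def create(
        cls,
        entry_id: int,
        qry_id: int,
        ref_id: int,
        qry_interval: tuple[float, float],
        ref_interval: tuple[float, float],
        orientation: str,
        confidence: float,
        **kw,
    ) -> "MapAlignment":
        """Build a record from ascending intervals, applying the disk
        convention for the query span of ``-`` alignments."""
        qlo, qhi = sorted(qry_interval)
        rlo, rhi = sorted(ref_interval)
        if orientation == "-":
            qs, qe = qhi, qlo
        else:
            qs, qe = qlo, qhi
        return cls(entry_id, qry_id, ref_id, qs, qe, rlo, rhi, orientation,
                   confidence, **kw)

    @property
    def qry_lo(self) -> float:
        return min(self.qry_start, self.qry_end)

    @property
    def qry_hi(self) -> float:
        return max(self.qry_start, self.qry_end)

    @property
    def ref_span(self) -> float:
        return self.ref_end - self.ref_start

    @property
    def qry_span(self) -> float:
        return self.qry_hi - self.qry_lo

    def validate(self) -> None:
        if self.orientation not in ("+", "-"):
            raise InvariantError(f"alignment {self.entry_id}: bad orientation")
        if not self.ref_start < self.ref_end:
            raise InvariantError(
                f"alignment {self.entry_id}: ref span must be ascending"
            )
        if self.orientation == "+" and not self.qry_start < self.qry_end:
            raise InvariantError(
                f"alignment {self.entry_id}: '+' query span must be ascending"
            )
        if self.orientation == "-" and not self.qry_start > self.qry_end:
            raise InvariantError(
                f"alignment {self.entry_id}: '-' query span must be stored descending"
            )


@dataclass
class AgpRecord:
    """One AGP v2.0 line (component ``W`` or gap ``N``/``U``)."""

    object_id: str
    object_start: int
    object_end: int
    part_number: int
    component_type: str  # W, N or U
    # W fields
    component_id: str | None = None
    component_start: int | None = None
    component_end: int | None = None
    orientation: str | None = None
    # gap fields
    gap_length: int | None = None
    gap_type: str = "scaffold"
    linkage: str = "yes"
    evidence: str = "map"

    @property
    def is_gap(self) -> bool:
        return self.component_type in ("N", "U")

    def to_line(self) -> str:
        if self.is_gap:
            tail = [str(self.gap_length), self.gap_type, self.linkage, self.evidence]
        else:
            tail = [self.component_id, str(self.component_start),
                    str(self.component_end), self.orientation]
        return "\t".join(
            [self.object_id, str(self.object_start), str(self.object_end),
             str(self.part_number), self.component_type] + tail
        )


@dataclass
class KeyRow:
    """Digestion key row linking a CMAP id to its FASTA header and length."""

    cmap_id: int
    header: str
    length: int


# ---------------------------------------------------------------------------
# BNX
# ---------------------------------------------------------------------------

_BNX_HEADER = """\
# BNX File Version:\t1.2
# Label Channels:\t1
# Nickase Recognition Site 1:\tunknown
#0h\tLabelChannel\tMoleculeId\tLength\tAvgIntensity\tSNR\tNumberofLabels\tOriginalMoleculeId\tScanNumber\tScanDirection\tChipId\tFlowcell\tRunId\tGlobalScanNumber
#0f\tint\tint\tfloat\tfloat\tfloat\tint\tint\tint\tint\tstring\tint\tint\tint
#1h\tLabelChannel\tLabelPositions[N]
#1f\tint\tfloat
"""


def read_bnx(path: str | Path) -> list[MoleculeMap]:
    """Parse a BNX 1.x file into :class:`MoleculeMap` records.

    One molecule per ``0``-line block; ``1``-line label positions are parsed
    (the conventional trailing molecule-length value is stripped); any other
    block rows (quality ``QX`` rows, extra channels) are preserved verbatim
    in ``extra_rows``.
    """
    molecules: list[MoleculeMap] = []
    current: MoleculeMap | None = None
    default_scan = 1
    default_flowcell = "1"
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                # run-data headers may carry a flowcell / run id fallback
                if line.lower().startswith("# run data"):
                    default_scan = 1
                continue
            tag, _, rest = line.partition("\t")
            if tag == "0":
                cols = rest.split("\t")
                try:
                    mol_id = int(cols[0])
                    length = float(cols[1])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{path}:{lineno}: malformed 0 line") from exc
                scan = default_scan
                flowcell = default_flowcell
                if len(cols) > 6:
                    try:
                        scan = int(cols[6])
                    except ValueError as exc:
                        raise ParseError(f"{path}:{lineno}: bad scan number") from exc
                if len(cols) > 9:
                    flowcell = cols[9]
                current = MoleculeMap(mol_id, length, [], scan, flowcell, [])
                molecules.append(current)
            elif tag == "1":
                if current is None:
                    raise ParseError(
                        f"{path}:{lineno}: '1' line before any '0' header line"
                    )
                try:
                    vals = [float(v) for v in rest.split("\t") if v != ""]
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric label position"
                    ) from exc
                # the 1-line conventionally ends with the molecule length
                if vals and abs(vals[-1] - current.length) < 1e-6:
                    vals = vals[:-1]
                current.label_positions = vals
            else:
                if current is None:
                    raise ParseError(
                        f"{path}:{lineno}: block row before any '0' header line"
                    )
                current.extra_rows.append(line)
    return molecules


def write_bnx(molecules: Iterable[MoleculeMap], path: str | Path) -> None:
    """Write molecules as BNX 1.2.  Refuses records that violate the
    molecule-map invariants, naming the offending molecule id."""
    molecules = list(molecules)
    for m in molecules:
        m.validate()
    with open(path, "w") as fh:
        fh.write(_BNX_HEADER)
        for m in molecules:
            fh.write(
                "0\t{id}\t{length:.1f}\t0.0\t0.0\t{n}\t{id}\t{scan}\t-1\t"
                "{flowcell}\t{flowcell}\t1\t{scan}\n".format(
                    id=m.molecule_id, length=m.length,
                    n=len(m.label_positions), scan=m.scan_id,
                    flowcell=m.flowcell_id,
                )
            )
            pos = list(m.label_positions) + [m.length]
            fh.write("1\t" + "\t".join(f"{p:.1f}" for p in pos) + "\n")
            for row in m.extra_rows:
                fh.write(row + "\n")


# ---------------------------------------------------------------------------
# CMAP
# ---------------------------------------------------------------------------

_CMAP_HEADER = """\
# CMAP File Version:\t0.1
# Label Channels:\t1
#h\tCMapId\tContigLength\tNumSites\tSiteID\tLabelChannel\tPosition\tStdDev\tCoverage\tOccurrence
#f\tint\tfloat\tint\tint\tint\tfloat\tfloat\tfloat\tfloat
"""


def read_cmap(path: str | Path) -> list[ConsensusMap]:
    """Parse a CMAP 0.1 file.

    The trailing channel-0 end marker per map is stripped; a missing end
    marker is tolerated with a warning.  A ``NumSites`` value that disagrees
    with the actual site rows is an error.
    """
    maps: dict[int, ConsensusMap] = {}
    declared: dict[int, int] = {}
    saw_marker: dict[int, bool] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 CMAP columns")
            try:
                cmap_id = int(cols[0])
                contig_length = float(cols[1])
                num_sites = int(cols[2])
                site_id = int(cols[3])
                channel = int(cols[4])
                position = float(cols[5])
                stddev = float(cols[6])
                coverage = float(cols[7])
                occurrence = float(cols[8])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric CMAP field") from exc
            cm = maps.get(cmap_id)
            if cm is None:
                cm = ConsensusMap(cmap_id, contig_length, [])
                maps[cmap_id] = cm
                declared[cmap_id] = num_sites
                saw_marker[cmap_id] = False
            if channel == 0:
                saw_marker[cmap_id] = True
                continue
            cm.sites.append(
                CmapSite(site_id, channel, position, stddev, coverage, occurrence)
            )
    for cmap_id, cm in maps.items():
        if cm.num_sites != declared[cmap_id]:
            raise ParseError(
                f"{path}: cmap {cmap_id}: NumSites={declared[cmap_id]} but "
                f"{cm.num_sites} site rows present"
            )
        if not saw_marker[cmap_id]:
            warnings.warn(
                f"cmap {cmap_id}: missing channel-0 end marker; reconstructed",
                stacklevel=2,
            )
    return list(maps.values())


def write_cmap(maps: Iterable[ConsensusMap], path: str | Path) -> None:
    maps = list(maps)
    for cm in maps:
        cm.validate()
    with open(path, "w") as fh:
        fh.write(_CMAP_HEADER)
        for cm in maps:
            n = cm.num_sites
            for s in cm.sites:
                fh.write(
                    f"{cm.cmap_id}\t{cm.contig_length:.1f}\t{n}\t{s.site_id}\t"
                    f"{s.channel}\t{s.position:.1f}\t{s.stddev:.1f}\t"
                    f"{s.coverage:.1f}\t{s.occurrence:.1f}\n"
                )
            # channel-0 end marker at the contig length
            fh.write(
                f"{cm.cmap_id}\t{cm.contig_length:.1f}\t{n}\t{n + 1}\t0\t"
                f"{cm.contig_length:.1f}\t0.0\t1.0\t1.0\n"
            )


# ---------------------------------------------------------------------------
# XMAP
# ---------------------------------------------------------------------------

_XMAP_COLUMNS = [
    "XmapEntryID", "QryContigID", "RefContigID", "QryStartPos", "QryEndPos",
    "RefStartPos", "RefEndPos", "Orientation", "Confidence", "HitEnum",
    "QryLen", "RefLen", "LabelChannel", "Alignment",
]

_XMAP_HEADER = (
    "# XMAP File Version:\t0.2\n"
    "#h\t" + "\t".join(_XMAP_COLUMNS) + "\n"
    "#f\tint\tint\tint\tfloat\tfloat\tfloat\tfloat\tstring\tfloat\tstring"
    "\tfloat\tfloat\tint\tstring\n"
)


def _parse_label_pairs(text: str) -> list[tuple[int, int]]:
    pairs = []
    for chunk in text.replace("(", " ").split(")"):
        chunk = chunk.strip()
        if not chunk:
            continue
        r, q = chunk.split(",")
        pairs.append((int(r), int(q)))
    return pairs


def _format_label_pairs(pairs: Sequence[tuple[int, int]]) -> str:
    return "".join(f"({r},{q})" for r, q in pairs)


def read_xmap(path: str | Path) -> list[MapAlignment]:
    """Parse an XMAP 0.2 file (9 mandatory columns, optional HitEnum /
    QryLen / RefLen / LabelChannel / Alignment columns)."""
    out: list[MapAlignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                missing = _XMAP_COLUMNS[len(cols)]
                raise ParseError(
                    f"{path}:{lineno}: record missing mandatory column "
                    f"'{missing}'"
                )
            orientation = cols[7]
            if orientation not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: unknown orientation token {orientation!r}"
                )
            try:
                aln = MapAlignment(
                    entry_id=int(cols[0]),
                    qry_id=int(cols[1]),
                    ref_id=int(cols[2]),
                    qry_start=float(cols[3]),
                    qry_end=float(cols[4]),
                    ref_start=float(cols[5]),
                    ref_end=float(cols[6]),
                    orientation=orientation,
                    confidence=float(cols[8]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric XMAP field") from exc
            if len(cols) > 9:
                aln.hit_enum = cols[9]
            if len(cols) > 10 and cols[10] not in ("", "-"):
                aln.qry_len = float(cols[10])
            if len(cols) > 11 and cols[11] not in ("", "-"):
                aln.ref_len = float(cols[11])
            if len(cols) > 12:
                aln.label_channel = cols[12]
            if len(cols) > 13:
                aln.label_pairs = _parse_label_pairs(cols[13])
            out.append(aln)
    return out


def write_xmap(alignments: Iterable[MapAlignment], path: str | Path) -> None:
    alignments = list(alignments)
    for a in alignments:
        a.validate()
    with open(path, "w") as fh:
        fh.write(_XMAP_HEADER)
        for a in alignments:
            fh.write(
                f"{a.entry_id}\t{a.qry_id}\t{a.ref_id}\t{a.qry_start:.1f}\t"
                f"{a.qry_end:.1f}\t{a.ref_start:.1f}\t{a.ref_end:.1f}\t"
                f"{a.orientation}\t{a.confidence:.2f}\t{a.hit_enum}\t"
                f"{'' if a.qry_len is None else format(a.qry_len, '.1f')}\t"
                f"{'' if a.ref_len is None else format(a.ref_len, '.1f')}\t"
                f"{a.label_channel}\t{_format_label_pairs(a.label_pairs)}\n"
            )


# ---------------------------------------------------------------------------
# FASTA (thin Biopython wrappers)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{header: sequence}`` mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seq_records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in items]
    SeqIO.write(seq_records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# digestion key file
# ---------------------------------------------------------------------------

_KEY_HEADER = "CompntId\tCompntName\tCompntLength"


def read_key(path: str | Path) -> list[KeyRow]:
    rows: list[KeyRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("CompntId"):
                continue
            cmap_id, header, length = line.split("\t")
            rows.append(KeyRow(int(cmap_id), header, int(length)))
    return rows


def write_key(rows: Iterable[KeyRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_KEY_HEADER + "\n")
        for r in rows:
            fh.write(f"{r.cmap_id}\t{r.header}\t{r.length}\n")


# ---------------------------------------------------------------------------
# AGP
# ---------------------------------------------------------------------------


def validate_agp(records: Sequence[AgpRecord]) -> None:
    """Assert the AGP tiling invariant: parts of each object cover
    ``[1, object_end]`` contiguously without overlap."""
    by_object: dict[str, list[AgpRecord]] = {}
    for rec in records:
        by_object.setdefault(rec.object_id, []).append(rec)
    for obj, parts in by_object.items():
        parts = sorted(parts, key=lambda r: r.part_number)
        cursor = 1
        for part in parts:
            if part.object_start != cursor:
                raise InvariantError(
                    f"AGP object {obj}: part {part.part_number} starts at "
                    f"{part.object_start}, expected {cursor}"
                )
            span = part.object_end - part.object_start + 1
            if part.is_gap:
                if span != part.gap_length:
                    raise InvariantError(
                        f"AGP object {obj}: gap span != gap_length"
                    )
                if part.component_type == "U" and part.gap_length != 100:
                    raise InvariantError(
                        f"AGP object {obj}: U gaps must be exactly 100 bp"
                    )
            else:
                if span != part.component_end - part.component_start + 1:
                    raise InvariantError(
                        f"AGP object {obj}: component span mismatch"
                    )
            cursor = part.object_end + 1


def write_agp(records: Sequence[AgpRecord], path: str | Path) -> None:
    validate_agp(records)
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_agp(path: str | Path) -> list[AgpRecord]:
    records: list[AgpRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            rec = AgpRecord(
                object_id=cols[0],
                object_start=int(cols[1]),
                object_end=int(cols[2]),
                part_number=int(cols[3]),
                component_type=cols[4],
            )
            if rec.is_gap:
                rec.gap_length = int(cols[5])
                rec.gap_type = cols[6]
                rec.linkage = cols[7]
                rec.evidence = cols[8] if len(cols) > 8 else "map"
            else:
                rec.component_id = cols[5]
                rec.component_start = int(cols[6])
                rec.component_end = int(cols[7])
                rec.orientation = cols[8]
            records.append(rec)
    return records


def reconstruct_fasta(records: Sequence[AgpRecord],
                      components: dict[str, str]) -> dict[str, str]:
    """Rebuild object sequences from AGP records plus component sequences.

    Used both for emitting super-scaffold FASTA and as the independent check
    that AGP and FASTA outputs agree byte-for-byte.
    """
    validate_agp(records)
    by_object: dict[str, list[AgpRecord]] = {}
    for rec in records:
        by_object.setdefault(rec.object_id, []).append(rec)
    out: dict[str, str] = {}
    for obj, parts in by_object.items():
        chunks: list[str] = []
        for part in sorted(parts, key=lambda r: r.part_number):
            if part.is_gap:
                chunks.append("N" * part.gap_length)
            else:
                if part.component_id not in components:
                    raise KeyError(
                        f"AGP object {obj} references unknown component "
                        f"{part.component_id!r}"
                    )
                seq = components[part.component_id]
                piece = seq[part.component_start - 1: part.component_end]
                if part.orientation == "-":
                    piece = reverse_complement(piece)
                chunks.append(piece)
        out[obj] = "".join(chunks)
    return out
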