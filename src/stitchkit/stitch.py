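"""Stitch: super-scaffold a draft FASTA from map alignments.

The external aligner is run with the *in silico* maps as reference and the
consensus genome maps as query; Stitch inverts that XMAP so the consensus
map becomes the scaffolding coordinate system, then:

1. filters alignments by confidence and by the percent of the total
   possible (overlap-limited) alignment length that is aligned (PAT) — an
   alignment passes if it satisfies *any* of the configured filter sets;
2. keeps only consensus maps to which at least two distinct in silico maps
   align, and for each in silico map selects the single longest alignment
   (ties: highest confidence, then smallest consensus map id / entry id);
3. orders the chosen scaffolds by their projected position on the consensus
   map (aligned span extended by the unaligned scaffold overhangs) and
   infers the signed gap between neighbours;
4. emits super-scaffold FASTA + AGP: positive gaps become runs of N with an
   AGP ``N`` line, negative or unknown gaps become a fixed 100 bp spacer
   with an AGP ``U`` line;
5. flags partial alignments (PAT below 60 %) and extreme negative gaps
   (below −20 kb) for sequence-level review; optionally (the v1.4.5
   behaviour) excludes both flanks of a sub-threshold negative gap from
   joining.

Only one alignment per in silico map is used per iteration; iteration is
driven by :mod:`stitchkit.pipeline`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .formats import (
    AgpRecord,
    InvariantError,
    KeyRow,
    MapAlignment,
    reverse_complement,
)

SPACER_LENGTH = 100  # bp of N inserted for negative/unknown gaps


@dataclass
class AlignmentFilterSet:
    min_confidence: float  # -log10 p-value units
    min_pat: float         # percent of total possible aligned length

    def __post_init__(self) -> None:
        if not 0 <= self.min_pat <= 100:
            raise ValueError("min_pat must be in [0, 100]")
        if self.min_confidence < 0:
            raise ValueError("min_confidence must be >= 0")


DEFAULT_FILTER_SETS = (AlignmentFilterSet(13.0, 30.0),
                       AlignmentFilterSet(8.0, 90.0))


@dataclass
class StitchConfig:
    filter_sets: tuple[AlignmentFilterSet, ...] = DEFAULT_FILTER_SETS
    partial_pat_threshold: float = 60.0
    negative_gap_flag_limit: float = -20_000.0
    min_negative_gap_exclusion: float | None = None  # v1.4.5 opt-in
    spacer_length: int = SPACER_LENGTH

    def __post_init__(self) -> None:
        if self.spacer_length != SPACER_LENGTH:
            raise ValueError("spacer length is fixed at 100 bp")
        if not 0 < self.partial_pat_threshold < 100:
            raise ValueError("partial PAT threshold must be in (0, 100)")
        if not self.filter_sets:
            raise ValueError("at least one filter set required")


@dataclass
class ScaffoldingAlignment:
    """A passing alignment decorated with PAT, scaffold overhangs, and the
    projected interval on the consensus map.

    After inversion the reference is the consensus map and the query is the
    in silico (scaffold) map.  Overhangs are the unaligned scaffold lengths
    taken in alignment orientation; the projected interval extends the
    aligned reference span by them, placing the whole scaffold on the
    consensus map under the 1 bp scaffold ≙ 1 bp map assumption.
    """

    alignment: MapAlignment
    pat: float
    leading_overhang: float
    trailing_overhang: float
    projected_start: float
    projected_end: float

    @property
    def consensus_id(self) -> int:
        return self.alignment.ref_id

    @property
    def insilico_id(self) -> int:
        return self.alignment.qry_id


@dataclass
class JoinRecord:
    consensus_id: int
    left_insilico: int
    right_insilico: int
    gap: float
    left_pat: float
    right_pat: float
    left_confidence: float
    right_confidence: float


@dataclass
class FlagRecord:
    kind: str  # partial_alignment | extreme_negative_gap | excluded_join
    consensus_id: int
    insilico_ids: tuple[int, ...]
    detail: str


@dataclass
class SuperScaffoldPlan:
    name: str
    consensus_id: int
    components: list[tuple[int, str]]  # (insilico cmap id, orientation)
    gaps: list[float]                  # signed, len == len(components) - 1


@dataclass
class StitchResult:
    fasta: dict[str, str]
    agp: list[AgpRecord]
    plans: list[SuperScaffoldPlan]
    joins: list[JoinRecord]
    flags: list[FlagRecord]
    n_new_joins: int
    next_counter: int


# ---------------------------------------------------------------------------
# inversion
# ---------------------------------------------------------------------------


def invert_xmap(alignments: Iterable[MapAlignment]) -> list[MapAlignment]:
    """Swap query and reference roles, re-establishing the stored-coordinate
    convention (descending span for '-') on the new query side, and sort by
    the new reference id and start (stable)."""
    out = []
    for a in alignments:
        if a.qry_len is None or a.ref_len is None:
            raise ValueError(
                f"alignment {a.entry_id}: QryLen/RefLen required to invert"
            )
        out.append(MapAlignment.create(
            entry_id=a.entry_id,
            qry_id=a.ref_id,
            ref_id=a.qry_id,
            qry_interval=(a.ref_start, a.ref_end),
            ref_interval=(a.qry_lo, a.qry_hi),
            orientation=a.orientation,
            confidence=a.confidence,
            hit_enum=a.hit_enum,
            qry_len=a.ref_len,
            ref_len=a.qry_len,
            label_channel=a.label_channel,
            label_pairs=[(q, r) for r, q in a.label_pairs],
        ))
    out.sort(key=lambda a: (a.ref_id, a.ref_start))
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _oriented_qry_overhangs(a: MapAlignment) -> tuple[float, float]:
    """Unaligned query lengths on each side, in alignment orientation: for
    '-' the query's high end leads (maps to the reference start side)."""
    if a.qry_len is None:
        raise ValueError(f"alignment {a.entry_id}: QryLen required")
    left = a.qry_lo
    right = a.qry_len - a.qry_hi
    if a.orientation == "-":
        left, right = right, left
    return left, right


def percent_aligned(a: MapAlignment) -> float:
    """Percent of the total possible (overlap-limited) alignment length that
    is aligned.

    The total possible length is the aligned reference span plus, on each
    side, the smaller of the reference and query overhangs (query overhangs
    taken in alignment orientation).  A true overlap or containment scores
    100; an interior local alignment scores low.
    """
    if a.ref_len is None or a.qry_len is None:
        raise ValueError(f"alignment {a.entry_id}: QryLen/RefLen required")
    aligned = a.ref_span
    if aligned <= 0:
        raise ValueError(f"alignment {a.entry_id}: zero aligned span")
    r_left = a.ref_start
    r_right = a.ref_len - a.ref_end
    q_left, q_right = _oriented_qry_overhangs(a)
    total_possible = aligned + min(r_left, q_left) + min(r_right, q_right)
    return 100.0 * aligned / total_possible


def make_scaffolding_alignment(a: MapAlignment) -> ScaffoldingAlignment:
    pat = percent_aligned(a)
    lead, trail = _oriented_qry_overhangs(a)
    return ScaffoldingAlignment(
        alignment=a,
        pat=pat,
        leading_overhang=lead,
        trailing_overhang=trail,
        projected_start=a.ref_start - lead,
        projected_end=a.ref_end + trail,
    )


def filter_alignments(
    alignments: Iterable[MapAlignment],
    filter_sets: Sequence[AlignmentFilterSet] = DEFAULT_FILTER_SETS,
) -> list[ScaffoldingAlignment]:
    """Keep alignments passing any filter set (confidence >= min AND
    PAT >= min, boundaries inclusive); PAT is computed once and attached."""
    if not filter_sets:
        raise ValueError("at least one filter set required")
    passing = []
    for a in alignments:
        sa = make_scaffolding_alignment(a)
        if any(a.confidence >= fs.min_confidence and sa.pat >= fs.min_pat
               for fs in filter_sets):
            passing.append(sa)
    return passing


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def select_scaffolding_alignments(
    passing: Sequence[ScaffoldingAlignment],
) -> list[ScaffoldingAlignment]:
    """At most one alignment per in silico map.

    Scaffolding candidates are alignments on consensus maps to which at
    least two distinct in silico maps align.  Per in silico map the longest
    aligned consensus-map span wins; ties go to the highest confidence, then
    deterministically to the smallest (consensus map id, entry id).
    Consensus maps left with fewer than two chosen scaffolds yield no joins
    this iteration (handled downstream).
    """
    by_consensus: dict[int, set[int]] = {}
    for sa in passing:
        by_consensus.setdefault(sa.consensus_id, set()).add(sa.insilico_id)
    candidates = [sa for sa in passing
                  if len(by_consensus[sa.consensus_id]) >= 2]
    best: dict[int, ScaffoldingAlignment] = {}
    for sa in candidates:
        cur = best.get(sa.insilico_id)
        if cur is None:
            best[sa.insilico_id] = sa
            continue
        key = (-sa.alignment.ref_span, -sa.alignment.confidence,
               sa.consensus_id, sa.alignment.entry_id)
        cur_key = (-cur.alignment.ref_span, -cur.alignment.confidence,
                   cur.consensus_id, cur.alignment.entry_id)
        if key < cur_key:
            best[sa.insilico_id] = sa
    return sorted(best.values(),
                  key=lambda sa: (sa.consensus_id, sa.projected_start,
                                  sa.projected_end))


# ---------------------------------------------------------------------------
# gap inference
# ---------------------------------------------------------------------------


@dataclass
class ConsensusPlan:
    """Ordered scaffolds and signed gaps along one consensus map."""

    consensus_id: int
    chosen: list[ScaffoldingAlignment]
    gaps: list[float]


def infer_gaps(chosen: Sequence[ScaffoldingAlignment]) -> ConsensusPlan:
    """Order >= 2 chosen scaffolds on one consensus map by projected start
    and infer the signed gap between neighbours."""
    if len(chosen) < 2:
        raise ValueError("need at least two chosen alignments to infer gaps")
    consensus_ids = {sa.consensus_id for sa in chosen}
    if len(consensus_ids) != 1:
        raise ValueError("chosen alignments span multiple consensus maps")
    ordered = sorted(chosen, key=lambda sa: (sa.projected_start,
                                             sa.projected_end))
    gaps = [nxt.projected_start - cur.projected_end
            for cur, nxt in zip(ordered, ordered[1:])]
    return ConsensusPlan(consensus_ids.pop(), ordered, gaps)


# ---------------------------------------------------------------------------
# flags
# ---------------------------------------------------------------------------


def flag_issues(
    plans: Sequence[ConsensusPlan],
    passing: Sequence[ScaffoldingAlignment],
    config: StitchConfig,
) -> tuple[list[FlagRecord], set[int]]:
    """Partial-alignment and extreme-negative-gap flags, plus the set of in
    silico maps excluded from joining when the v1.4.5 minimum-negative-gap
    filter is enabled."""
    flags: list[FlagRecord] = []
    excluded: set[int] = set()
    for sa in passing:
        if sa.pat < config.partial_pat_threshold:
            flags.append(FlagRecord(
                "partial_alignment", sa.consensus_id, (sa.insilico_id,),
                f"PAT {sa.pat:.1f}% < {config.partial_pat_threshold}%"))
    for plan in plans:
        for (left, right), gap in zip(
                zip(plan.chosen, plan.chosen[1:]), plan.gaps):
            pair = (left.insilico_id, right.insilico_id)
            if gap < config.negative_gap_flag_limit:
                flags.append(FlagRecord(
                    "extreme_negative_gap", plan.consensus_id, pair,
                    f"gap {gap:.0f} bp < {config.negative_gap_flag_limit:.0f} bp"))
            if (config.min_negative_gap_exclusion is not None
                    and gap < config.min_negative_gap_exclusion):
                excluded.update(pair)
                flags.append(FlagRecord(
                    "excluded_join", plan.consensus_id, pair,
                    f"gap {gap:.0f} bp < minimum negative gap "
                    f"{config.min_negative_gap_exclusion:.0f} bp; both maps "
                    f"excluded this iteration"))
    return flags, excluded


# ---------------------------------------------------------------------------
# building
# ---------------------------------------------------------------------------


def build_super_scaffolds(
    plans: Sequence[ConsensusPlan],
    scaffolds: dict[str, str],
    key_rows: Sequence[KeyRow],
    config: StitchConfig,
    counter_start: int = 1,
) -> StitchResult:
    """Concatenate planned components into super-scaffold FASTA + AGP.

    '-' components are reverse-complemented; positive gaps become runs of N
    of the estimated (rounded) length; negative or zero gaps become the
    fixed 100 bp spacer with an AGP ``U`` line.  Scaffolds not in any plan
    pass through unchanged, in input order, as single-component objects.
    """
    id_to_header = {k.cmap_id: k.header for k in key_rows}
    fasta: dict[str, str] = {}
    agp: list[AgpRecord] = []
    joins: list[JoinRecord] = []
    used: set[str] = set()
    counter = counter_start

    for plan in plans:
        if len(plan.chosen) < 2:
            continue
        name = f"Super_scaffold_{counter}"
        counter += 1
        chunks: list[str] = []
        parts: list[AgpRecord] = []
        cursor = 1
        part_no = 1
        for idx, sa in enumerate(plan.chosen):
            header = id_to_header.get(sa.insilico_id)
            if header is None:
                raise KeyError(
                    f"in silico map {sa.insilico_id} not present in the "
                    f"digestion key")
            if header not in scaffolds:
                raise KeyError(f"missing sequence for scaffold {header!r}")
            if idx > 0:
                gap = plan.gaps[idx - 1]
                if gap > 0:
                    gap_len = max(1, round(gap))
                    gap_type = "N"
                else:
                    gap_len = config.spacer_length
                    gap_type = "U"
                chunks.append("N" * gap_len)
                parts.append(AgpRecord(
                    name, cursor, cursor + gap_len - 1, part_no, gap_type,
                    gap_length=gap_len))
                cursor += gap_len
                part_no += 1
                prev = plan.chosen[idx - 1]
                joins.append(JoinRecord(
                    plan.consensus_id, prev.insilico_id, sa.insilico_id,
                    gap, prev.pat, sa.pat, prev.alignment.confidence,
                    sa.alignment.confidence))
            seq = scaffolds[header]
            orientation = sa.alignment.orientation
            chunks.append(seq if orientation == "+"
                          else reverse_complement(seq))
            parts.append(AgpRecord(
                name, cursor, cursor + len(seq) - 1, part_no, "W",
                component_id=header, component_start=1,
                component_end=len(seq), orientation=orientation))
            cursor += len(seq)
            part_no += 1
            used.add(header)
        fasta[name] = "".join(chunks)
        agp.extend(parts)

    for header, seq in scaffolds.items():
        if header in used:
            continue
        fasta[header] = seq
        agp.append(AgpRecord(header, 1, len(seq), 1, "W",
                             component_id=header, component_start=1,
                             component_end=len(seq), orientation="+"))

    # reorder: super scaffolds first (AGP grouped per object already)
    n_new_joins = len(joins)
    plan_objects = [
        SuperScaffoldPlan(
            name=obj,
            consensus_id=plan.consensus_id,
            components=[(sa.insilico_id, sa.alignment.orientation)
                        for sa in plan.chosen],
            gaps=list(plan.gaps),
        )
        for obj, plan in zip(
            (o for o in fasta if o.startswith("Super_scaffold_")),
            [p for p in plans if len(p.chosen) >= 2])
    ]
    return StitchResult(fasta, agp, plan_objects, joins, [], n_new_joins,
                        counter)


# ---------------------------------------------------------------------------
# one full pass
# ---------------------------------------------------------------------------


def stitch_once(
    scaffolds: dict[str, str],
    inverted_alignments: Sequence[MapAlignment],
    key_rows: Sequence[KeyRow],
    config: StitchConfig | None = None,
    counter_start: int = 1,
) -> StitchResult:
    """One Stitch pass: filter → select → infer gaps → flag → build."""
    config = config or StitchConfig()
    known = {k.cmap_id for k in key_rows}
    unresolved = sorted({a.qry_id for a in inverted_alignments} - known)
    if unresolved:
        raise KeyError(
            f"alignment query ids not in the digestion key: {unresolved}")

    passing = filter_alignments(inverted_alignments, config.filter_sets)
    chosen = select_scaffolding_alignments(passing)

    by_consensus: dict[int, list[ScaffoldingAlignment]] = {}
    for sa in chosen:
        by_consensus.setdefault(sa.consensus_id, []).append(sa)
    plans = [infer_gaps(group) for group in by_consensus.values()
             if len(group) >= 2]

    flags, excluded = flag_issues(plans, passing, config)
    if excluded:
        pruned = []
        for plan in plans:
            keep = [sa for sa in plan.chosen if sa.insilico_id not in excluded]
            if len(keep) >= 2:
                pruned.append(infer_gaps(keep))
        plans = pruned

    result = build_super_scaffolds(plans, scaffolds, key_rows, config,
                                   counter_start)
    result.flags = flags
    return result
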