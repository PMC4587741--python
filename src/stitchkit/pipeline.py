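"""Sewing machine: iterate digest → align → invert → stitch to a fixpoint.

Each iteration digests the current FASTA into *in silico* maps, aligns the
consensus genome maps to them (the aligner is pluggable: an external
command's XMAP or one of the simulator's stand-ins), inverts the alignment,
and runs one Stitch pass.  Iteration stops when a pass creates no new joins
or after ``max_iter`` passes (default 5).  Because later passes may join
super-scaffolds created earlier, the final AGP is flattened so every object
references only original input scaffolds, with orientations composed
(− of − is +).

The aligner protocol is ``aligner(ref_maps, qry_maps, context)`` returning
``MapAlignment`` records with the in silico maps as reference.  ``context``
carries the digestion key rows, the current object → original-component
registry, and the iteration number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .digest import DigestConfig, digest_fasta
from .formats import AgpRecord, ConsensusMap, KeyRow, MapAlignment
from .stats import n50
from .stitch import StitchConfig, StitchResult, invert_xmap, stitch_once

Aligner = Callable[
    [Sequence[ConsensusMap], Sequence[ConsensusMap], dict],
    list[MapAlignment],
]


def _flip(orientation: str) -> str:
    return "-" if orientation == "+" else "+"


def compose_orientations(outer: str, inner: str) -> str:
    """Orientation of a nested component: − ∘ − = +."""
    return inner if outer == "+" else _flip(inner)


@dataclass
class IterationRecord:
    iteration: int
    n_records: int
    n50: float
    total_length: float
    n_new_joins: int


@dataclass
class PipelineResult:
    fasta: dict[str, str]
    agp: list[AgpRecord]
    report: pd.DataFrame
    iterations: list[StitchResult] = field(default_factory=list)
    components: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# AGP flattening
# ---------------------------------------------------------------------------


def flatten_agp(
    records: Sequence[AgpRecord],
    original_ids: set[str] | None = None,
) -> list[AgpRecord]:
    """Flatten nested AGP records so objects reference only original
    components.

    ``records`` may describe objects whose W components are themselves
    objects described elsewhere in ``records`` (from earlier iterations).
    Only top-level objects (never used as a component) are emitted;
    coordinates and part numbers are recomputed and gap lines preserved.
    Placing an object with orientation '-' reverses its part order and flips
    component orientations.
    """
    by_object: dict[str, list[AgpRecord]] = {}
    for rec in records:
        by_object.setdefault(rec.object_id, []).append(rec)
    for parts in by_object.values():
        parts.sort(key=lambda r: r.part_number)

    referenced = {rec.component_id for rec in records
                  if not rec.is_gap and rec.component_id in by_object
                  and rec.component_id != rec.object_id}

    def resolve(obj: str, orientation: str,
                stack: tuple[str, ...]) -> list[AgpRecord]:
        """Flattened parts of ``obj`` as placed with ``orientation``
        (coordinates unset; W parts carry only component fields)."""
        if obj in stack:
            raise RuntimeError(f"cycle in AGP registry at {obj!r}")
        parts = by_object[obj]
        flat: list[AgpRecord] = []
        ordered = parts if orientation == "+" else list(reversed(parts))
        for part in ordered:
            if part.is_gap:
                flat.append(AgpRecord(
                    "", 0, 0, 0, part.component_type,
                    gap_length=part.gap_length, gap_type=part.gap_type,
                    linkage=part.linkage, evidence=part.evidence))
            else:
                comp_orient = (part.orientation if orientation == "+"
                               else _flip(part.orientation))
                comp = part.component_id
                if (comp in by_object and comp != obj
                        and (original_ids is None
                             or comp not in original_ids)):
                    flat.extend(resolve(comp, comp_orient, stack + (obj,)))
                else:
                    flat.append(AgpRecord(
                        "", 0, 0, 0, "W", component_id=comp,
                        component_start=part.component_start,
                        component_end=part.component_end,
                        orientation=comp_orient))
        return flat

    tops = [obj for obj in by_object if obj not in referenced]
    if by_object and not tops:
        raise RuntimeError("cycle in AGP registry: no top-level object")
    out: list[AgpRecord] = []
    for obj in tops:
        cursor = 1
        for part_no, part in enumerate(resolve(obj, "+", ()), start=1):
            part.object_id = obj
            part.part_number = part_no
            if part.is_gap:
                span = part.gap_length
            else:
                span = part.component_end - part.component_start + 1
            part.object_start = cursor
            part.object_end = cursor + span - 1
            cursor += span
            out.append(part)
    return out


# ---------------------------------------------------------------------------
# iteration driver
# ---------------------------------------------------------------------------


def run_iterations(
    fasta: Mapping[str, str],
    consensus_maps: Sequence[ConsensusMap],
    aligner: Aligner,
    digest_config: DigestConfig | None = None,
    stitch_config: StitchConfig | None = None,
    max_iter: int = 5,
) -> PipelineResult:
    """Iterate digest → align → invert → stitch until no new joins.

    Returns the final FASTA, an AGP flattened to the original input
    scaffolds, a per-iteration report (record count, N50, total length,
    new joins), and the per-iteration stitch results.
    """
    digest_config = digest_config or DigestConfig()
    stitch_config = stitch_config or StitchConfig()
    current: dict[str, str] = dict(fasta)
    original_ids = set(current)
    # flattened registry: every current object -> [(original id, orientation)]
    registry: dict[str, list[tuple[str, str]]] = {
        name: [(name, "+")] for name in current
    }
    all_agp: list[AgpRecord] = []
    iteration_results: list[StitchResult] = []
    report_rows: list[IterationRecord] = []
    counter = 1

    for iteration in range(1, max_iter + 1):
        insilico, key_rows, _ = digest_fasta(current, digest_config)
        context = {
            "key": key_rows,
            "components": {name: list(parts)
                           for name, parts in registry.items()},
            "iteration": iteration,
        }
        try:
            raw = aligner(insilico, list(consensus_maps), context)
        except Exception as exc:
            raise RuntimeError(
                f"aligner failed at iteration {iteration}: {exc}") from exc
        inverted = invert_xmap(raw)
        result = stitch_once(current, inverted, key_rows, stitch_config,
                             counter_start=counter)
        counter = result.next_counter
        iteration_results.append(result)

        # update the flattened registry and collect this pass's AGP
        id_to_header = {k.cmap_id: k.header for k in key_rows}
        new_registry: dict[str, list[tuple[str, str]]] = {}
        for plan in result.plans:
            flat: list[tuple[str, str]] = []
            for insilico_id, orientation in plan.components:
                header = id_to_header[insilico_id]
                inner = registry.get(header, [(header, "+")])
                if orientation == "+":
                    flat.extend(inner)
                else:
                    flat.extend((oid, _flip(o)) for oid, o in reversed(inner))
            new_registry[plan.name] = flat
        for name in result.fasta:
            if name not in new_registry:
                new_registry[name] = registry.get(name, [(name, "+")])
        registry = new_registry
        # collect only the AGP of super scaffolds created this pass;
        # passthrough lines are re-emitted every pass and would duplicate
        new_objects = {plan.name for plan in result.plans}
        all_agp.extend(rec for rec in result.agp
                       if rec.object_id in new_objects)

        current = result.fasta
        lengths = [len(s) for s in current.values()]
        report_rows.append(IterationRecord(
            iteration, len(current), float(n50(lengths)),
            float(sum(lengths)), result.n_new_joins))
        if result.n_new_joins == 0:
            break

    # add single-component lines for surviving pass-through objects, then
    # flatten so every final object references only original scaffolds
    described = {rec.object_id for rec in all_agp}
    for name, seq in current.items():
        if name not in described:
            all_agp.append(AgpRecord(name, 1, len(seq), 1, "W",
                                     component_id=name, component_start=1,
                                     component_end=len(seq), orientation="+"))
    final_agp = flatten_agp(all_agp, original_ids=original_ids)
    final_agp = [rec for rec in final_agp if rec.object_id in current]
    report = pd.DataFrame([vars(r) for r in report_rows])
    return PipelineResult(current, final_agp, report, iteration_results,
                          registry)
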