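"""Assembly parameter sweep: thresholds, staging, and candidate ranking.

De novo map assembly is run externally (the assembler is proprietary); this
module computes the p-value threshold triple from the estimated genome
length, stages the sweep (first a threshold round at the default minimum
molecule length, then a minimum-length round around the best threshold —
three to nine assemblies in total), emits declarative run configs, and
scores/ranks candidate assemblies afterwards.

The default threshold is ``numerator / genome length (Mb)`` with strict =
default/10 and relaxed = default×10.  The default numerator of 1e-6
reproduces the canonical triple (5e-10, 5e-09, 5e-08) for a 200 Mb genome
and is configurable.

Candidate selection follows two ideals: the cumulative map length should
match the estimated haploid genome length, and the maps should align to the
in silico maps with minimal redundancy.  Ranking is assistive — the full
table is reported so a human can override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .stats import AlignmentCoverage, MapSetStats

DEFAULT_THRESHOLD_NUMERATOR = 1e-6  # per Mb of genome
DEFAULT_MINLEN = 150_000
MINLEN_VARIANTS = (100_000, 180_000)


@dataclass
class SweepConfig:
    genome_length_mb: float
    threshold_numerator: float = DEFAULT_THRESHOLD_NUMERATOR
    minlen_default: int = DEFAULT_MINLEN
    minlen_variants: tuple[int, ...] = MINLEN_VARIANTS

    def __post_init__(self) -> None:
        if self.genome_length_mb <= 0:
            raise ValueError("genome length must be > 0 Mb")
        if self.threshold_numerator <= 0:
            raise ValueError("threshold numerator must be > 0")


@dataclass
class ThresholdTriple:
    relaxed: float
    default: float
    strict: float


@dataclass
class AssemblyRunConfig:
    name: str
    p_value_threshold: float
    min_molecule_length: int
    stage: str


@dataclass
class AssemblyScore:
    name: str
    cumulative_length: float
    genome_length_delta: float
    breadth: float
    redundancy: float
    rank_key: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        ratio = (self.redundancy / self.breadth
                 if self.breadth > 0 else math.inf)
        delta_ratio = self.genome_length_delta
        self.rank_key = (ratio, delta_ratio)


def compute_thresholds(config: SweepConfig) -> ThresholdTriple:
    """Threshold triple for a genome length: default = numerator/Mb,
    strict = default/10, relaxed = default*10."""
    default = config.threshold_numerator / config.genome_length_mb
    return ThresholdTriple(relaxed=default * 10, default=default,
                           strict=default / 10)


def plan_sweep(
    config: SweepConfig,
    stage: str = "first-round",
    best_first_round_t: float | None = None,
) -> list[AssemblyRunConfig]:
    """Stage the sweep.

    ``first-round``: the three threshold variants at the default minimum
    molecule length (150 kb).  ``minlen-round``: the best first-round
    threshold at each minimum-length variant (100 and 180 kb).
    """
    if stage == "first-round":
        triple = compute_thresholds(config)
        return [
            AssemblyRunConfig("relaxed_t", triple.relaxed,
                              config.minlen_default, stage),
            AssemblyRunConfig("default_t", triple.default,
                              config.minlen_default, stage),
            AssemblyRunConfig("strict_t", triple.strict,
                              config.minlen_default, stage),
        ]
    if stage == "minlen-round":
        if best_first_round_t is None:
            raise ValueError("minlen-round requires the best first-round "
                             "threshold")
        return [
            AssemblyRunConfig(f"best_t_minlen_{ml // 1000}k",
                              best_first_round_t, ml, stage)
            for ml in config.minlen_variants
        ]
    raise ValueError(f"unknown stage {stage!r}")


def write_run_configs(configs: Sequence[AssemblyRunConfig],
                      out_dir: str | Path) -> list[Path]:
    """Emit one declarative YAML run config per assembly; invoking the
    external assembler on them is the user's step."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cfg in configs:
        path = out_dir / f"{cfg.name}.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump({
                "name": cfg.name,
                "stage": cfg.stage,
                "p_value_threshold": cfg.p_value_threshold,
                "min_molecule_length": cfg.min_molecule_length,
            }, fh, sort_keys=False)
        paths.append(path)
    return paths


def score_assembly(
    name: str,
    candidate_stats: MapSetStats,
    coverage: AlignmentCoverage,
    genome_length_bp: float,
) -> AssemblyScore:
    """Score one candidate consensus-map assembly against the genome-length
    and alignment-redundancy ideals."""
    return AssemblyScore(
        name=name,
        cumulative_length=candidate_stats.cumulative_length,
        genome_length_delta=abs(candidate_stats.cumulative_length
                                - genome_length_bp) / genome_length_bp,
        breadth=coverage.breadth,
        redundancy=coverage.redundancy,
    )


def rank_assemblies(
    scores: Sequence[AssemblyScore],
    primary: str = "redundancy",
) -> tuple[list[AssemblyScore], pd.DataFrame]:
    """Order candidates (stable sort) and report the full table.

    ``primary='redundancy'`` sorts by (redundancy ratio, genome-length
    delta); ``primary='length'`` swaps the two keys.  Zero-breadth
    candidates rank last.
    """
    if not scores:
        raise ValueError("need at least one candidate")
    if primary == "redundancy":
        key = lambda s: s.rank_key
    elif primary == "length":
        key = lambda s: (s.rank_key[1], s.rank_key[0])
    else:
        raise ValueError("primary must be 'redundancy' or 'length'")
    ranked = sorted(scores, key=key)
    table = pd.DataFrame([
        {
            "name": s.name,
            "cumulative_length": s.cumulative_length,
            "genome_length_delta": s.genome_length_delta,
            "breadth": s.breadth,
            "redundancy": s.redundancy,
            "redundancy_ratio": s.rank_key[0],
        }
        for s in ranked
    ])
    return ranked, table
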