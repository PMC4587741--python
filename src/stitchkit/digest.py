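"""In silico digestion: convert sequence scaffolds to label maps.

A nicking endonuclease recognizes a short motif (defaults: nt.BspQI
``GCTCTTC`` and nt.BbvCI ``CCTCAGC``).  A scaffold's *in silico* map is the
sorted list of motif occurrences on either strand, reported as the 1-based
coordinate of the leftmost base of the match on the forward strand.  Only
scaffolds longer than 20 kb with more than 5 labels qualify for a map; the
rest are excluded and reported with the rule they failed.

Label density (labels per 100 kb) is the quality metric used to choose
enzymes; the ideal band is 10–15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats import ConsensusMap, CmapSite, KeyRow, reverse_complement

IDEAL_DENSITY_BAND = (10.0, 15.0)

NT_BSPQI = "GCTCTTC"
NT_BBVCI = "CCTCAGC"


@dataclass
class DigestConfig:
    """Inclusion rules and motifs for in silico digestion.

    ``min_scaffold_length`` and ``min_labels`` are strict minima: a scaffold
    qualifies only if it is *longer than* ``min_scaffold_length`` and has
    *more than* ``min_labels`` labels.
    """

    motifs: tuple[str, ...] = (NT_BSPQI, NT_BBVCI)
    min_scaffold_length: int = 20_000
    min_labels: int = 5
    channel_mode: str = "merged"  # or "per-enzyme"

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("at least one motif required")
        for m in self.motifs:
            if not m or set(m) - set("ACGT"):
                raise ValueError(f"motif must be non-empty uppercase ACGT: {m!r}")
        if self.min_scaffold_length <= 0:
            raise ValueError("min_scaffold_length must be > 0")
        if self.channel_mode not in ("merged", "per-enzyme"):
            raise ValueError("channel_mode must be 'merged' or 'per-enzyme'")


@dataclass
class ExcludedScaffold:
    header: str
    length: int
    n_labels: int
    failed_rule: str


@dataclass
class DensityReport:
    overall: float
    per_channel: dict[int, float] = field(default_factory=dict)
    in_ideal_band: bool = False


def _find_forward(seq: str, motif: str) -> list[int]:
    # overlapping occurrences: advance by one after each hit
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(start + 1)  # 1-based leftmost base
        start = seq.find(motif, start + 1)
    return hits


def find_label_sites(sequence: str, motif: str) -> list[int]:
    """All occurrences of ``motif`` on either strand of ``sequence``.

    Each site is the 1-based coordinate of the leftmost base of the match on
    the forward strand.  Characters outside A/C/G/T (e.g. N) never match.
    Palindromic motifs are reported once per genomic occurrence.
    """
    if not motif:
        raise ValueError("empty motif")
    seq = sequence.upper()
    motif = motif.upper()
    hits = set(_find_forward(seq, motif))
    rc = reverse_complement(motif)
    if rc != motif:  # palindromic double-count guard
        hits.update(_find_forward(seq, rc))
    return sorted(hits)


def digest_sequence(sequence: str,
                    motifs: tuple[str, ...]) -> list[tuple[int, int]]:
    """Merged digestion: sorted ``(position, channel)`` pairs, channel being
    the 1-based motif index (all collapsed to channel 1 by callers in merged
    mode)."""
    sites: list[tuple[int, int]] = []
    for channel, motif in enumerate(motifs, start=1):
        sites.extend((p, channel) for p in find_label_sites(sequence, motif))
    sites.sort()
    return sites


def digest_fasta(
    scaffolds: dict[str, str],
    config: DigestConfig | None = None,
) -> tuple[list[ConsensusMap], list[KeyRow], list[ExcludedScaffold]]:
    """Digest sequence scaffolds into *in silico* maps.

    Returns the maps for qualifying scaffolds (cmap ids assigned 1..n in
    input order), key rows mapping cmap id to FASTA header and length, and
    the excluded scaffolds with the rule each failed.
    """
    config = config or DigestConfig()
    if len(set(scaffolds)) != len(scaffolds):
        raise ValueError("duplicate scaffold ids")
    maps: list[ConsensusMap] = []
    key: list[KeyRow] = []
    excluded: list[ExcludedScaffold] = []
    next_id = 1
    for header, seq in scaffolds.items():
        length = len(seq)
        sites = digest_sequence(seq, config.motifs)
        if length <= config.min_scaffold_length:
            excluded.append(ExcludedScaffold(
                header, length, len(sites),
                f"length {length} not > {config.min_scaffold_length}"))
            continue
        if len(sites) <= config.min_labels:
            excluded.append(ExcludedScaffold(
                header, length, len(sites),
                f"{len(sites)} labels not > {config.min_labels}"))
            continue
        cmap_sites = []
        for site_id, (pos, channel) in enumerate(sites, start=1):
            chan = channel if config.channel_mode == "per-enzyme" else 1
            cmap_sites.append(CmapSite(site_id, chan, float(pos)))
        maps.append(ConsensusMap(next_id, float(length), cmap_sites))
        key.append(KeyRow(next_id, header, length))
        next_id += 1
    return maps, key, excluded


def label_density(maps: list[ConsensusMap]) -> DensityReport:
    """Labels per 100 kb over a map set, overall and per label channel.

    Also reports whether the overall density falls in the ideal band
    [10, 15] (closed interval).
    """
    if not maps:
        raise ValueError("label_density requires at least one map")
    total_length = sum(m.contig_length for m in maps)
    if total_length <= 0:
        raise ValueError("zero total map length")
    total_sites = sum(m.num_sites for m in maps)
    per_channel: dict[int, int] = {}
    for m in maps:
        for s in m.sites:
            per_channel[s.channel] = per_channel.get(s.channel, 0) + 1
    overall = 1e5 * total_sites / total_length
    lo, hi = IDEAL_DENSITY_BAND
    return DensityReport(
        overall=overall,
        per_channel={c: 1e5 * n / total_length for c, n in sorted(per_channel.items())},
        in_ideal_band=lo <= overall <= hi,
    )
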