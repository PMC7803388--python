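"""Split-read detection and integration-site calling.

A transgene insertion produces reads that straddle the vector–genome
junction: a local aligner maps one part of such a read to a genome
scaffold and the rest to the vector scaffold, recording the partner
placement in the SA:Z tag.  The caller walks the alignments, keeps split
reads whose halves both pass the quality filter (MAPQ > 30 and NM < 4 by
default), computes the exact junction coordinate on each reference from
the CIGAR, tabulates unique per-junction support with read pairs counted
once, and calls integration sites above a support threshold (15 for a
deep single-sample run, 5 for multiplexed samples).

Junction coordinate rule: the SAM position is the leftmost aligned base,
so when the CIGAR starts with aligned bases the junction lies at
``pos + reference_span`` (just past the aligned block), and when it starts
with a clip the junction is the reported position itself.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .alignment import (
    AlignmentRecord,
    CigarOp,
    ReferenceSet,
    SupplementaryEntry,
    clip_lengths,
    reference_span,
)
from .errors import ConfigurationError, InconsistentEvidenceError, ReferenceMismatchError

__all__ = [
    "CallerConfig",
    "AlignedPart",
    "SplitReadEvidence",
    "JunctionCandidate",
    "IntegrationSite",
    "FilterFunnel",
    "junction_position",
    "extract_split_evidence",
    "tabulate",
    "call_sites",
    "call_integration_sites",
]

PROFILES = {"deep": 15, "multiplex": 5}


@dataclass(frozen=True)
class CallerConfig:
    """Filter and threshold settings for integration-site calling.

    ``min_mapq`` keeps alignments with MAPQ strictly greater, ``max_nm``
    keeps alignments with NM strictly smaller — the strict inequalities
    mirror the published filter (MAPQ > 30, NM < 4).
    """

    vector_name: str = "vector"
    min_support: int = 5
    min_mapq: int = 30
    max_nm: int = 4
    merge_window: int = 0
    skip_duplicates: bool = True

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ConfigurationError("min_support must be >= 1")
        if self.min_mapq < 0:
            raise ConfigurationError("min_mapq must be >= 0")
        if self.max_nm < 1:
            raise ConfigurationError("max_nm must be >= 1")
        if self.merge_window < 0:
            raise ConfigurationError("merge_window must be >= 0")

    @classmethod
    def profile(cls, name: str, **overrides) -> "CallerConfig":
        """Named operating point: "deep" (min_support 15) or "multiplex" (5)."""
        try:
            min_support = PROFILES[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown profile {name!r}; choose from {sorted(PROFILES)}"
            ) from None
        overrides.setdefault("min_support", min_support)
        return cls(**overrides)

    def replace(self, **changes) -> "CallerConfig":
        return dataclasses.replace(self, **changes)


class AlignedPart(NamedTuple):
    """One half of a split alignment, on either the genome or the vector."""

    refname: str
    pos: int
    strand: str
    cigar: tuple[CigarOp, ...]
    mapq: int
    nm: int | None


@dataclass(frozen=True)
class SplitReadEvidence:
    """One read's vector–genome split alignment and derived junction."""

    qname: str
    mate: int
    genome_part: AlignedPart
    vector_part: AlignedPart
    genome_junction: int
    vector_junction: int
    vector_end: str  # "left" | "right": which vector terminus abuts the genome


@dataclass(frozen=True)
class JunctionCandidate:
    """A unique junction with its supporting read identifiers.

    Supporters are a set of query names, so both mates of a pair — or a
    primary record and its mirrored supplementary record — contribute a
    single count.
    """

    scaffold: str
    genome_pos: int
    vector_pos: int
    vector_end: str
    supporters: frozenset[str]
    strands: frozenset[str] = frozenset()

    @property
    def support(self) -> int:
        return len(self.supporters)

    @property
    def key(self) -> tuple:
        return (self.scaffold, self.genome_pos, self.vector_pos, self.vector_end)


@dataclass(frozen=True)
class IntegrationSite:
    """A called vector–genome junction (1-based genome coordinate)."""

    sample: str
    scaffold: str
    genome_pos: int
    vector_pos: int
    vector_end: str
    strand: str
    support: int
    supporters: frozenset[str] = frozenset()


@dataclass
class FilterFunnel:
    """Per-stage record counts so every filtering step is auditable."""

    parsed: int = 0
    duplicates_skipped: int = 0
    secondary_skipped: int = 0
    unmapped_skipped: int = 0
    no_sa: int = 0
    not_vector_genome: int = 0
    mapq_failed: int = 0
    nm_failed: int = 0
    split_evidence: int = 0

    def as_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def junction_position(
    pos: int, cigar: Sequence[CigarOp], junction_side: str
) -> int:
    """Junction coordinate implied by one half of a split alignment.

    ``junction_side`` names the end of the alignment (in reference
    orientation) whose clipped bases belong to the partner reference.
    A left-side junction is the reported position itself (the first
    aligned base); a right-side junction adds the reference span to the
    position.  Deletions and skips shift the reference coordinate, so the
    full reference span is used, not just the leading match length.
    """
    left, right = clip_lengths(tuple(cigar))
    if junction_side == "left":
        if left == 0:
            raise InconsistentEvidenceError(
                "junction claimed on left but CIGAR has no left clip"
            )
        return pos
    if junction_side == "right":
        if right == 0:
            raise InconsistentEvidenceError(
                "junction claimed on right but CIGAR has no right clip"
            )
        return pos + reference_span(cigar)
    raise ValueError(f"junction_side must be 'left' or 'right', got {junction_side!r}")


def _junction_side(cigar: Sequence[CigarOp]) -> str:
    """Which end of the alignment abuts the partner reference.

    The clipped end is the partner's share of the read; with clips at both
    ends the larger clip wins (the shorter one is typically adapter or
    microhomology trim). Ties break to the left for determinism.
    """
    left, right = clip_lengths(tuple(cigar))
    if left == 0 and right == 0:
        raise InconsistentEvidenceError("split alignment has no clipped end")
    return "left" if left >= right else "right"


def _part_junction(part: AlignedPart) -> int:
    return junction_position(part.pos, part.cigar, _junction_side(part.cigar))


def _passes_quality(mapq: int, nm: int | None, config: CallerConfig) -> tuple[bool, str]:
    """Apply the MAPQ/NM filter to one alignment half.

    Records lacking an NM tag fail the NM filter: the filter is explicit,
    so an absent value cannot be assumed to be zero.
    """
    if not mapq > config.min_mapq:
        return False, "mapq"
    if nm is None or not nm < config.max_nm:
        return False, "nm"
    return True, ""


def _vector_end(vector_junction: int, refs: ReferenceSet) -> str:
    """Label which terminus of the linearized vector abuts the genome."""
    return "left" if 2 * vector_junction <= refs.vector_length else "right"


def extract_split_evidence(
    record: AlignmentRecord,
    refs: ReferenceSet,
    config: CallerConfig,
    funnel: FilterFunnel | None = None,
) -> SplitReadEvidence | None:
    """Derive junction evidence from one record and its SA entries.

    Returns evidence iff the record and one SA entry land on the vector
    scaffold and a genome scaffold (in either direction) and *both* halves
    pass the MAPQ/NM filter; otherwise ``None``.  Secondary alignments and
    (by default) duplicate-flagged records are ignored.
    """

    def bump(attr: str) -> None:
        if funnel is not None:
            setattr(funnel, attr, getattr(funnel, attr) + 1)

    if record.is_unmapped:
        bump("unmapped_skipped")
        return None
    if record.is_secondary:
        bump("secondary_skipped")
        return None
    if config.skip_duplicates and record.is_duplicate:
        bump("duplicates_skipped")
        return None
    if not record.sa_entries:
        bump("no_sa")
        return None

    record_part = AlignedPart(
        refname=record.refname,
        pos=record.pos,
        strand=record.strand,
        cigar=record.cigar,
        mapq=record.mapq,
        nm=record.nm,
    )
    record_on_vector = refs.is_vector(record.refname)
    if not record_on_vector and record.refname not in refs.scaffold_names:
        raise ReferenceMismatchError(f"record on unknown scaffold {record.refname!r}")

    chosen: tuple[AlignedPart, AlignedPart] | None = None
    for sa in record.sa_entries:
        if sa.rname not in refs.all_names:
            raise ReferenceMismatchError(
                f"SA entry of {record.qname!r} names unknown scaffold {sa.rname!r}"
            )
        sa_on_vector = refs.is_vector(sa.rname)
        if record_on_vector == sa_on_vector:
            continue  # genome-genome or vector-vector chimera
        sa_part = AlignedPart(sa.rname, sa.pos, sa.strand, sa.cigar, sa.mapq, sa.nm)
        if record_on_vector:
            chosen = (sa_part, record_part)  # (genome, vector)
        else:
            chosen = (record_part, sa_part)
        break
    if chosen is None:
        bump("not_vector_genome")
        return None

    genome_part, vector_part = chosen
    for part in (genome_part, vector_part):
        ok, why = _passes_quality(part.mapq, part.nm, config)
        if not ok:
            bump("mapq_failed" if why == "mapq" else "nm_failed")
            return None

    genome_junction = _part_junction(genome_part)
    vector_junction = _part_junction(vector_part)
    bump("split_evidence")
    return SplitReadEvidence(
        qname=record.qname,
        mate=record.mate,
        genome_part=genome_part,
        vector_part=vector_part,
        genome_junction=genome_junction,
        vector_junction=vector_junction,
        vector_end=_vector_end(vector_junction, refs),
    )


def tabulate(evidences: Iterable[SplitReadEvidence]) -> list[JunctionCandidate]:
    """Tabulate unique-junction support, counting each read pair once.

    Junctions are keyed by (scaffold, genome position, vector position,
    vector end); supporters are distinct query names, so mates of a pair
    supporting the same junction are a single count.
    """
    supporters: dict[tuple, set[str]] = defaultdict(set)
    strands: dict[tuple, set[str]] = defaultdict(set)
    for ev in evidences:
        key = (
            ev.genome_part.refname,
            ev.genome_junction,
            ev.vector_junction,
            ev.vector_end,
        )
        supporters[key].add(ev.qname)
        strands[key].add(ev.genome_part.strand)
    return [
        JunctionCandidate(
            scaffold=key[0],
            genome_pos=key[1],
            vector_pos=key[2],
            vector_end=key[3],
            supporters=frozenset(supporters[key]),
            strands=frozenset(strands[key]),
        )
        for key in sorted(supporters)
    ]


def _merge_cluster(cluster: list[JunctionCandidate]) -> JunctionCandidate:
    """Collapse near-identical junction positions into one candidate.

    The merged position is the support-weighted mode of member positions
    (ties to the smallest coordinate); supporters are unioned.
    """
    pos_support: dict[int, set[str]] = defaultdict(set)
    for cand in cluster:
        pos_support[cand.genome_pos] |= cand.supporters
    best_pos = max(sorted(pos_support), key=lambda p: (len(pos_support[p]), -p))
    at_best = [c for c in cluster if c.genome_pos == best_pos]
    rep = max(at_best, key=lambda c: (c.support, -c.vector_pos))
    all_supporters = frozenset().union(*(c.supporters for c in cluster))
    all_strands = frozenset().union(*(c.strands for c in cluster))
    return JunctionCandidate(
        scaffold=rep.scaffold,
        genome_pos=best_pos,
        vector_pos=rep.vector_pos,
        vector_end=rep.vector_end,
        supporters=all_supporters,
        strands=all_strands,
    )


def call_sites(
    candidates: Iterable[JunctionCandidate],
    config: CallerConfig,
    sample: str = "sample",
) -> list[IntegrationSite]:
    """Threshold candidates into called integration sites.

    With ``merge_window > 0`` candidates on the same scaffold and vector
    end whose positions chain within the window are merged before
    thresholding.  A candidate is called when support >= ``min_support``
    ("a minimum of N reads or pairs" is read inclusively).  Output is
    sorted by (scaffold, genome position, vector end).
    """
    cands = list(candidates)
    if config.merge_window > 0:
        merged: list[JunctionCandidate] = []
        groups: dict[tuple[str, str], list[JunctionCandidate]] = defaultdict(list)
        for cand in cands:
            groups[(cand.scaffold, cand.vector_end)].append(cand)
        for group_key in sorted(groups):
            members = sorted(groups[group_key], key=lambda c: c.genome_pos)
            cluster = [members[0]]
            for cand in members[1:]:
                if cand.genome_pos - cluster[-1].genome_pos <= config.merge_window:
                    cluster.append(cand)
                else:
                    merged.append(_merge_cluster(cluster))
                    cluster = [cand]
            merged.append(_merge_cluster(cluster))
        cands = merged

    sites = [
        IntegrationSite(
            sample=sample,
            scaffold=cand.scaffold,
            genome_pos=cand.genome_pos,
            vector_pos=cand.vector_pos,
            vector_end=cand.vector_end,
            strand="/".join(sorted(cand.strands)) or "+",
            support=cand.support,
            supporters=cand.supporters,
        )
        for cand in cands
        if cand.support >= config.min_support
    ]
    sites.sort(key=lambda s: (s.scaffold, s.genome_pos, s.vector_end))
    return sites


def call_integration_sites(
    records: Iterable[AlignmentRecord],
    refs: ReferenceSet,
    config: CallerConfig,
    sample: str = "sample",
) -> tuple[list[IntegrationSite], list[JunctionCandidate], FilterFunnel]:
    """End-to-end convenience: records -> evidence -> candidates -> sites."""
    funnel = FilterFunnel()
    evidences = []
    for record in records:
        funnel.parsed += 1
        ev = extract_split_evidence(record, refs, config, funnel=funnel)
        if ev is not None:
            evidences.append(ev)
    candidates = tabulate(evidences)
    sites = call_sites(candidates, config, sample=sample)
    return sites, candidates, funnel
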