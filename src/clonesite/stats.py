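"""Per-sample capture/enrichment statistics.

Hybridization capture with vector probes should concentrate sequencing on
fragments containing vector sequence.  The on-target fraction (pairs with
any alignment touching the vector scaffold, entirely or as a split) and
the enrichment ratio (vector-mapped over non-vector-mapped) summarise how
well that worked for a sample.  Counts are over unique read pairs, i.e.
after excluding duplicate-flagged records; read-level counterparts are
reported alongside because the two conventions differ in the literature.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .alignment import AlignmentRecord, ReferenceSet

__all__ = ["MappingStats", "compute_stats"]


@dataclass(frozen=True)
class MappingStats:
    """Mapping category counts and derived capture metrics for one sample.

    The three pair categories partition ``unique_read_pairs``.  When the
    denominator of a ratio is zero the value is reported as 0 (percent,
    with ``undefined`` set) or ``inf`` (enrichment over an all-vector
    library).
    """

    sample: str
    unique_read_pairs: int
    vector_pairs: int
    genome_only_pairs: int
    unmapped_pairs: int
    duplicate_pairs: int
    orphan_reads: int
    vector_reads: int
    nonvector_reads: int
    undefined: bool = False

    @property
    def pct_on_target(self) -> float:
        if self.unique_read_pairs == 0:
            return 0.0
        return 100.0 * self.vector_pairs / self.unique_read_pairs

    @property
    def enrichment_ratio(self) -> float:
        """Vector pairs over non-vector pairs (inf when nothing is off-target)."""
        other = self.unique_read_pairs - self.vector_pairs
        if other == 0:
            return math.inf if self.vector_pairs else 0.0
        return self.vector_pairs / other

    @property
    def pct_on_target_reads(self) -> float:
        total = self.vector_reads + self.nonvector_reads
        if total == 0:
            return 0.0
        return 100.0 * self.vector_reads / total

    @property
    def enrichment_ratio_reads(self) -> float:
        if self.nonvector_reads == 0:
            return math.inf if self.vector_reads else 0.0
        return self.vector_reads / self.nonvector_reads

    def as_dict(self) -> dict:
        d = {
            "sample": self.sample,
            "unique_read_pairs": self.unique_read_pairs,
            "vector_pairs": self.vector_pairs,
            "genome_only_pairs": self.genome_only_pairs,
            "unmapped_pairs": self.unmapped_pairs,
            "duplicate_pairs": self.duplicate_pairs,
            "orphan_reads": self.orphan_reads,
            "vector_reads": self.vector_reads,
            "nonvector_reads": self.nonvector_reads,
            "pct_on_target": self.pct_on_target,
            "enrichment_ratio": self.enrichment_ratio,
            "pct_on_target_reads": self.pct_on_target_reads,
            "enrichment_ratio_reads": self.enrichment_ratio_reads,
            "undefined": self.undefined,
        }
        # JSON has no Infinity; serialise the sentinel as a string
        for key in ("enrichment_ratio", "enrichment_ratio_reads"):
            if math.isinf(d[key]):
                d[key] = "inf"
        return d


def _touches_vector(record: AlignmentRecord, refs: ReferenceSet) -> bool:
    if not record.is_unmapped and refs.is_vector(record.refname):
        return True
    return any(refs.is_vector(sa.rname) for sa in record.sa_entries)


def compute_stats(
    records: Iterable[AlignmentRecord],
    refs: ReferenceSet,
    sample: str = "sample",
) -> MappingStats:
    """Classify each unique read pair into exactly one mapping category.

    A pair is on-target if any mate's primary or SA alignment touches the
    vector scaffold; otherwise genome-only if any mate maps, else
    unmapped.  Pairs whose primary records are duplicate-flagged are
    excluded from the unique count.  Orphan reads (qnames seen on one mate
    only) are counted as single-read "pairs" with a warning.  The result
    is invariant to record order.
    """
    by_pair: dict[str, dict] = defaultdict(
        lambda: {"mates": set(), "vector_mates": set(), "dup": False, "mapped": False}
    )
    for record in records:
        if record.is_secondary or record.is_supplementary:
            # supplementary placement is already described by the primary's SA
            continue
        entry = by_pair[record.qname]
        entry["mates"].add(record.mate)
        if _touches_vector(record, refs):
            entry["vector_mates"].add(record.mate)
        entry["dup"] = entry["dup"] or record.is_duplicate
        entry["mapped"] = entry["mapped"] or not record.is_unmapped

    unique = vector = genome_only = unmapped = duplicates = 0
    orphans = 0
    vector_reads = nonvector_reads = 0
    for qname in by_pair:
        entry = by_pair[qname]
        n_mates = len(entry["mates"])
        if entry["dup"]:
            duplicates += 1
            continue
        if n_mates == 1:
            orphans += 1
        unique += 1
        n_vector = len(entry["vector_mates"])
        vector_reads += n_vector
        nonvector_reads += n_mates - n_vector
        if n_vector:
            vector += 1
        elif entry["mapped"]:
            genome_only += 1
        else:
            unmapped += 1
    if orphans:
        warnings.warn(
            f"{orphans} unpaired orphan read(s) counted as single-read pairs",
            stacklevel=2,
        )
    return MappingStats(
        sample=sample,
        unique_read_pairs=unique,
        vector_pairs=vector,
        genome_only_pairs=genome_only,
        unmapped_pairs=unmapped,
        duplicate_pairs=duplicates,
        orphan_reads=orphans,
        vector_reads=vector_reads,
        nonvector_reads=nonvector_reads,
        undefined=unique == 0,
    )
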