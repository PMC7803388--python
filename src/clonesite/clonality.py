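"""Clonality verification by integration-site set comparison.

Vector integration after transfection is effectively random, so two
independently derived cell lines are extremely unlikely to share even one
vector–genome junction.  Samples descending from one transfected ancestor
therefore carry the same set of integration sites, and comparing site
sets across samples both verifies clonal lineage and groups samples into
lineages.

Two sites match when they lie on the same scaffold with the same vector
end within a position tolerance (default 0 bp: junctions from the same
lineage agree at base resolution).  Within one sample, a (left, right)
vector-end pair a few hundred bp apart marks the two ends of a single
insertion, and extra junctions a few kbp from a main locus on the same
scaffold are flagged as rearrangement/duplication-linked rather than
independent integration events.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx

from .caller import IntegrationSite

__all__ = [
    "SiteKey",
    "SampleSiteSet",
    "PairwiseRelation",
    "LinkedPair",
    "LocusSummary",
    "ClonalityReport",
    "match_count",
    "compare_samples",
    "group_lineages",
    "annotate_linked_junctions",
    "build_report",
]

DEFAULT_TOLERANCE = 0
DEFAULT_END_PAIR_DISTANCE = 500
DEFAULT_LINK_DISTANCE = 10_000


class SiteKey(NamedTuple):
    """Identity of an integration site for cross-sample comparison."""

    scaffold: str
    genome_pos: int
    vector_end: str


@dataclass(frozen=True)
class SampleSiteSet:
    """A sample's clonal identity: its called sites with support counts."""

    sample_id: str
    sites: Mapping[SiteKey, int]  # key -> support

    @classmethod
    def from_sites(cls, sample_id: str, sites: Iterable[IntegrationSite]) -> "SampleSiteSet":
        collected: dict[SiteKey, int] = {}
        for site in sites:
            key = SiteKey(site.scaffold, site.genome_pos, site.vector_end)
            collected[key] = max(collected.get(key, 0), site.support)
        return cls(sample_id=sample_id, sites=collected)

    @property
    def keys(self) -> list[SiteKey]:
        return sorted(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def match_count(a: Sequence[SiteKey], b: Sequence[SiteKey], tolerance: int) -> int:
    """Maximum one-to-one matching between two site lists.

    Sites pair only within the same (scaffold, vector_end) and with
    |Δpos| <= tolerance.  Within each stratum the 1-D maximum matching is
    found greedily over position-sorted lists, which is optimal for
    interval matching on a line.
    """
    by_stratum_a: dict[tuple, list[int]] = defaultdict(list)
    by_stratum_b: dict[tuple, list[int]] = defaultdict(list)
    for key in a:
        by_stratum_a[(key.scaffold, key.vector_end)].append(key.genome_pos)
    for key in b:
        by_stratum_b[(key.scaffold, key.vector_end)].append(key.genome_pos)
    matched = 0
    for stratum, pos_a in by_stratum_a.items():
        pos_b = by_stratum_b.get(stratum)
        if not pos_b:
            continue
        pos_a = sorted(pos_a)
        pos_b = sorted(pos_b)
        i = j = 0
        while i < len(pos_a) and j < len(pos_b):
            if abs(pos_a[i] - pos_b[j]) <= tolerance:
                matched += 1
                i += 1
                j += 1
            elif pos_a[i] < pos_b[j]:
                i += 1
            else:
                j += 1
    return matched


@dataclass(frozen=True)
class PairwiseRelation:
    """Relation between two samples' site sets plus the Jaccard index."""

    sample_a: str
    sample_b: str
    relation: str  # identical | subset | partial | disjoint
    jaccard: float
    matched: int
    n_a: int
    n_b: int

    @property
    def consistent_with_same_lineage(self) -> bool:
        """Subset relations do not break clonality: a locus whose support
        fell below threshold in one sample is a missed call, not evidence
        of a different lineage."""
        return self.relation in ("identical", "subset")


def compare_samples(
    a: SampleSiteSet, b: SampleSiteSet, tolerance: int = DEFAULT_TOLERANCE
) -> PairwiseRelation:
    """Classify the relation between two samples' integration-site sets."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("compare_samples requires non-empty site sets")
    matched = match_count(a.keys, b.keys, tolerance)
    n_a, n_b = len(a), len(b)
    if matched == n_a == n_b:
        relation = "identical"
    elif matched == n_a or matched == n_b:
        relation = "subset"
    elif matched >= 1:
        relation = "partial"
    else:
        relation = "disjoint"
    jaccard = matched / (n_a + n_b - matched)
    return PairwiseRelation(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        relation=relation,
        jaccard=jaccard,
        matched=matched,
        n_a=n_a,
        n_b=n_b,
    )


def group_lineages(
    samples: Sequence[SampleSiteSet],
    tolerance: int = DEFAULT_TOLERANCE,
    min_shared: int = 1,
) -> list[list[str]]:
    """Partition samples into lineages by shared integration sites.

    Samples sharing at least ``min_shared`` matched sites are linked and
    lineages are the connected components of the link graph; one shared
    junction is the default evidence standard.  Output is deterministic:
    members sorted within groups, groups sorted by first member.
    """
    if not samples:
        raise ValueError("group_lineages requires at least one sample")
    graph = nx.Graph()
    graph.add_nodes_from(s.sample_id for s in samples)
    ordered = sorted(samples, key=lambda s: s.sample_id)
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if match_count(a.keys, b.keys, tolerance) >= min_shared:
                graph.add_edge(a.sample_id, b.sample_id)
    groups = [sorted(component) for component in nx.connected_components(graph)]
    groups.sort(key=lambda g: g[0])
    return groups


@dataclass(frozen=True)
class LinkedPair:
    """Two same-scaffold junctions annotated as one physical event."""

    site_a: SiteKey
    site_b: SiteKey
    distance: int
    kind: str  # "end_pair" | "linked"


@dataclass(frozen=True)
class LocusSummary:
    """Linked-junction annotation for one sample."""

    sample_id: str
    n_sites: int
    n_independent_loci: int
    pairs: tuple[LinkedPair, ...]


def annotate_linked_junctions(
    sites: SampleSiteSet,
    link_distance: int = DEFAULT_LINK_DISTANCE,
    end_pair_distance: int = DEFAULT_END_PAIR_DISTANCE,
) -> LocusSummary:
    """Collapse junction pairs that belong to one integration event.

    Two annotations are made per sample, per scaffold:

    * **end_pair** — opposite vector ends within ``end_pair_distance``
      are the two junctions of one insertion (observed tens of bp apart)
      and collapse to a single locus;
    * **linked** — a further junction within ``link_distance`` of a locus
      (observed ~1 kbp and ~4.7 kbp downstream) is flagged as a likely
      rearrangement/duplication of that locus, excluded from the count of
      independent loci but retained in the site table.
    """
    keys = sites.keys
    by_scaffold: dict[str, list[SiteKey]] = defaultdict(list)
    for key in keys:
        by_scaffold[key.scaffold].append(key)

    pairs: list[LinkedPair] = []
    n_loci = 0
    for scaffold in sorted(by_scaffold):
        members = sorted(by_scaffold[scaffold], key=lambda k: k.genome_pos)
        # 1) pair opposite vector ends within end_pair_distance (greedy nearest)
        used = [False] * len(members)
        loci: list[SiteKey] = []  # representative (leftmost) site per locus
        for i, key in enumerate(members):
            if used[i]:
                continue
            partner = None
            for j in range(i + 1, len(members)):
                if used[j]:
                    continue
                other = members[j]
                if other.genome_pos - key.genome_pos > end_pair_distance:
                    break
                if other.vector_end != key.vector_end:
                    partner = j
                    break
            if partner is not None:
                used[i] = used[partner] = True
                pairs.append(
                    LinkedPair(
                        site_a=key,
                        site_b=members[partner],
                        distance=members[partner].genome_pos - key.genome_pos,
                        kind="end_pair",
                    )
                )
                loci.append(key)
            else:
                used[i] = True
                loci.append(key)
        # 2) chain loci within link_distance: extras are linked, not independent
        cluster_rep: SiteKey | None = None
        for key in loci:
            if (
                cluster_rep is not None
                and key.genome_pos - cluster_rep.genome_pos <= link_distance
            ):
                pairs.append(
                    LinkedPair(
                        site_a=cluster_rep,
                        site_b=key,
                        distance=key.genome_pos - cluster_rep.genome_pos,
                        kind="linked",
                    )
                )
            else:
                cluster_rep = key
                n_loci += 1
    return LocusSummary(
        sample_id=sites.sample_id,
        n_sites=len(sites),
        n_independent_loci=n_loci,
        pairs=tuple(pairs),
    )


@dataclass(frozen=True)
class ClonalityReport:
    """Lineage partition, pairwise relations and locus annotations."""

    lineage_groups: tuple[tuple[str, ...], ...]
    pairwise: tuple[PairwiseRelation, ...]
    loci: tuple[LocusSummary, ...]
    tolerance: int
    min_shared: int
    link_distance: int
    end_pair_distance: int

    def as_dict(self) -> dict:
        return {
            "parameters": {
                "tolerance": self.tolerance,
                "min_shared": self.min_shared,
                "link_distance": self.link_distance,
                "end_pair_distance": self.end_pair_distance,
            },
            "lineage_groups": [list(g) for g in self.lineage_groups],
            "n_groups": len(self.lineage_groups),
            "pairwise": [
                {
                    "sample_a": r.sample_a,
                    "sample_b": r.sample_b,
                    "relation": r.relation,
                    "jaccard": r.jaccard,
                    "matched": r.matched,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                    "consistent_with_same_lineage": r.consistent_with_same_lineage,
                }
                for r in self.pairwise
            ],
            "loci": [
                {
                    "sample": s.sample_id,
                    "n_sites": s.n_sites,
                    "n_independent_loci": s.n_independent_loci,
                    "pairs": [
                        {
                            "site_a": list(p.site_a),
                            "site_b": list(p.site_b),
                            "distance": p.distance,
                            "kind": p.kind,
                        }
                        for p in s.pairs
                    ],
                }
                for s in self.loci
            ],
        }


def build_report(
    samples: Sequence[SampleSiteSet],
    tolerance: int = DEFAULT_TOLERANCE,
    min_shared: int = 1,
    link_distance: int = DEFAULT_LINK_DISTANCE,
    end_pair_distance: int = DEFAULT_END_PAIR_DISTANCE,
) -> ClonalityReport:
    """Full clonality analysis over a set of samples."""
    ordered = sorted(samples, key=lambda s: s.sample_id)
    groups = group_lineages(ordered, tolerance=tolerance, min_shared=min_shared)
    pairwise = [
        compare_samples(a, b, tolerance=tolerance)
        for i, a in enumerate(ordered)
        for b in ordered[i + 1 :]
    ]
    loci = [
        annotate_linked_junctions(
            s, link_distance=link_distance, end_pair_distance=end_pair_distance
        )
        for s in ordered
    ]
    return ClonalityReport(
        lineage_groups=tuple(tuple(g) for g in groups),
        pairwise=tuple(pairwise),
        loci=tuple(loci),
        tolerance=tolerance,
        min_shared=min_shared,
        link_distance=link_distance,
        end_pair_distance=end_pair_distance,
    )
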