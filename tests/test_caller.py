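"""Split-read evidence extraction, support tabulation and site calling."""

from __future__ import annotations

import random

import pytest

from clonesite.alignment import AlignmentRecord, ReferenceSet, parse_cigar
from clonesite.caller import (
    CallerConfig,
    JunctionCandidate,
    call_integration_sites,
    call_sites,
    extract_split_evidence,
    junction_position,
    tabulate,
)
from clonesite.errors import (
    ConfigurationError,
    InconsistentEvidenceError,
    ReferenceMismatchError,
)
from clonesite.simulate import preset, simulate_sam

REFS = ReferenceSet(
    scaffold_lengths={"scaffold_1": 50_000, "scaffold_2": 50_000},
    vector_name="vector",
    vector_length=8_000,
)
CONFIG = CallerConfig(vector_name="vector")


def split_record(
    qname="r1",
    flag=99,
    refname="scaffold_1",
    pos=1000,
    mapq=60,
    cigar="60M40S",
    nm=0,
    sa="vector,1,+,60S40M,60,0;",
):
    """A genome-side primary alignment whose SA names the vector scaffold."""
    from clonesite.alignment import parse_sa_tag

    return AlignmentRecord(
        qname=qname,
        flag=flag,
        refname=refname,
        pos=pos,
        mapq=mapq,
        cigar=parse_cigar(cigar),
        nm=nm,
        sa_entries=parse_sa_tag(sa) if sa else (),
    )


# --- junction_position ------------------------------------------------------


@pytest.mark.parametrize(
    "pos, cigar, side, expected",
    [
        (1000, "60M40S", "right", 1060),  # aligned bases first: add the span
        (5000, "40S60M", "left", 5000),  # clip first: position is the junction
        (200, "30M2D30M40S", "right", 262),  # deletion shifts the coordinate
        (200, "30M2I28M42S", "right", 258),  # insertions do not
    ],
)
def test_junction_position(pos, cigar, side, expected):
    assert junction_position(pos, parse_cigar(cigar), side) == expected


def test_junction_position_requires_clip_on_stated_side():
    with pytest.raises(InconsistentEvidenceError):
        junction_position(1000, parse_cigar("60M40S"), "left")
    with pytest.raises(InconsistentEvidenceError):
        junction_position(1000, parse_cigar("40S60M"), "right")


# --- extract_split_evidence -------------------------------------------------


def test_extracts_vector_genome_split():
    ev = extract_split_evidence(split_record(), REFS, CONFIG)
    assert ev is not None
    assert ev.genome_part.refname == "scaffold_1"
    assert ev.genome_junction == 1060
    assert ev.vector_junction == 1
    assert ev.vector_end == "left"  # vector position 1 is the low-coordinate terminus


def test_extracts_when_primary_is_on_vector():
    rec = split_record(
        refname="vector", pos=7800, cigar="60M40S",
        sa="scaffold_1,3000,+,60S40M,60,0;",
    )
    ev = extract_split_evidence(rec, REFS, CONFIG)
    assert ev is not None
    assert ev.genome_part.refname == "scaffold_1"
    assert ev.genome_junction == 3000
    assert ev.vector_junction == 7860
    assert ev.vector_end == "right"


def test_genome_only_chimera_yields_nothing():
    rec = split_record(sa="scaffold_2,500,+,60S40M,60,0;")
    assert extract_split_evidence(rec, REFS, CONFIG) is None


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(sa="vector,1,+,60S40M,20,0;"),  # vector-side MAPQ 20 fails > 30
        dict(mapq=30),  # boundary: 30 is not > 30
        dict(nm=4),  # boundary: 4 is not < 4
        dict(nm=None),  # absent NM fails the explicit NM filter
        dict(flag=99 | 0x400),  # duplicate-flagged
        dict(flag=99 | 0x100),  # secondary alignment ignored
        dict(flag=4, refname=None, pos=None, cigar="60M40S"),  # unmapped
        dict(sa=None),  # no SA: not a split read
    ],
)
def test_rejected_evidence(kwargs):
    cigar = kwargs.pop("cigar", "60M40S")
    rec = split_record(cigar=cigar, **kwargs)
    if rec.is_unmapped:
        rec = AlignmentRecord(qname="r1", flag=4, refname=None, pos=None, mapq=0, cigar=None)
    assert extract_split_evidence(rec, REFS, CONFIG) is None


def test_duplicates_kept_when_configured():
    rec = split_record(flag=99 | 0x400)
    config = CONFIG.replace(skip_duplicates=False)
    assert extract_split_evidence(rec, REFS, config) is not None


def test_unknown_sa_scaffold_raises():
    rec = split_record(sa="chr_unknown,5,+,60S40M,60,0;")
    with pytest.raises(ReferenceMismatchError):
        extract_split_evidence(rec, REFS, CONFIG)


# --- tabulate ---------------------------------------------------------------


def test_pair_counts_once():
    mate1 = split_record(qname="pair1", flag=99)
    mate2 = split_record(qname="pair1", flag=147)
    evs = [extract_split_evidence(r, REFS, CONFIG) for r in (mate1, mate2)]
    cands = tabulate(evs)
    assert len(cands) == 1
    assert cands[0].support == 1  # both mates of one pair: one count


def test_distinct_qnames_count_separately():
    evs = [
        extract_split_evidence(split_record(qname=q), REFS, CONFIG)
        for q in ("a", "b")
    ]
    cands = tabulate(evs)
    assert len(cands) == 1 and cands[0].support == 2


def test_tabulate_empty():
    assert tabulate([]) == []


# --- call_sites -------------------------------------------------------------


def make_candidate(pos, supporters, scaffold="scaffold_1", vector_pos=1, end="left"):
    return JunctionCandidate(
        scaffold=scaffold,
        genome_pos=pos,
        vector_pos=vector_pos,
        vector_end=end,
        supporters=frozenset(supporters),
        strands=frozenset("+"),
    )


def test_support_threshold_is_inclusive():
    config = CONFIG.replace(min_support=15)
    called = call_sites([make_candidate(100, [f"r{i}" for i in range(20)])], config)
    assert len(called) == 1
    not_called = call_sites([make_candidate(100, [f"r{i}" for i in range(14)])], config)
    assert not_called == []
    boundary = call_sites([make_candidate(100, [f"r{i}" for i in range(15)])], config)
    assert len(boundary) == 1


def test_merge_window_pools_support_before_threshold():
    # oracle (enumerated by hand on this 2-candidate instance): the cluster
    # {5000:4, 5002:3} merges into one candidate with 7 distinct supporters
    # at the support-weighted modal position 5000, which passes min_support 5
    cands = [
        make_candidate(5000, [f"a{i}" for i in range(4)]),
        make_candidate(5002, [f"b{i}" for i in range(3)]),
    ]
    config = CONFIG.replace(min_support=5, merge_window=5)
    sites = call_sites(cands, config)
    assert len(sites) == 1
    assert sites[0].genome_pos == 5000 and sites[0].support == 7
    # without merging neither candidate survives
    assert call_sites(cands, CONFIG.replace(min_support=5)) == []


def test_merge_tie_breaks_to_smallest_coordinate():
    cands = [
        make_candidate(5002, ["a", "b"]),
        make_candidate(5000, ["c", "d"]),
    ]
    sites = call_sites(cands, CONFIG.replace(min_support=4, merge_window=5))
    assert sites[0].genome_pos == 5000


def test_call_sites_idempotent_over_candidates():
    cands = [
        make_candidate(5000, [f"a{i}" for i in range(6)]),
        make_candidate(9000, [f"b{i}" for i in range(2)]),
    ]
    config = CONFIG.replace(min_support=5)
    once = call_sites(cands, config)
    again = call_sites(
        [
            make_candidate(s.genome_pos, s.supporters, s.scaffold, s.vector_pos, s.vector_end)
            for s in once
        ],
        config,
    )
    assert [(s.scaffold, s.genome_pos, s.support) for s in once] == [
        (s.scaffold, s.genome_pos, s.support) for s in again
    ]


def test_config_validation():
    with pytest.raises(ConfigurationError):
        CallerConfig(min_support=0)
    with pytest.raises(ConfigurationError):
        CallerConfig(max_nm=0)
    with pytest.raises(ConfigurationError):
        CallerConfig.profile("nonsense")
    assert CallerConfig.profile("deep").min_support == 15
    assert CallerConfig.profile("multiplex").min_support == 5


# --- pipeline properties on simulated data ----------------------------------


@pytest.fixture(scope="module")
def lineage_e_records():
    from clonesite.simulate import make_study_reference

    sequences, refs = make_study_reference(11)
    truths, config = preset("lineage_E")
    result = simulate_sam(truths, config.replace(seed=11), refs, sequences=sequences)
    return list(result.iter_records()), refs, truths


def site_keys(sites):
    return {(s.scaffold, s.genome_pos, s.vector_end) for s in sites}


def test_filter_monotonicity(lineage_e_records):
    records, refs, _ = lineage_e_records
    base = CallerConfig.profile("multiplex")
    baseline, _, _ = call_integration_sites(records, refs, base)
    for stricter in (
        base.replace(min_support=base.min_support + 5),
        base.replace(min_mapq=base.min_mapq + 30),
        base.replace(max_nm=1),
    ):
        sites, _, _ = call_integration_sites(records, refs, stricter)
        assert site_keys(sites) <= site_keys(baseline)


def test_support_conservation(lineage_e_records):
    records, refs, _ = lineage_e_records
    from clonesite.caller import FilterFunnel, extract_split_evidence

    evidences = [
        ev
        for rec in records
        if (ev := extract_split_evidence(rec, refs, CallerConfig.profile("multiplex")))
        is not None
    ]
    cands = tabulate(evidences)
    assert sum(c.support for c in cands) <= len({ev.qname for ev in evidences})


def test_recovery_at_exact_planted_coordinates(lineage_e_records):
    records, refs, truths = lineage_e_records
    sites, _, _ = call_integration_sites(records, refs, CallerConfig.profile("multiplex"))
    planted = {(t.scaffold, t.genome_pos, t.vector_end) for t in truths if not t.suppress_sa}
    assert site_keys(sites) == planted
    by_key = {(s.scaffold, s.genome_pos, s.vector_end): s for s in sites}
    for t in truths:
        if not t.suppress_sa:
            assert by_key[(t.scaffold, t.genome_pos, t.vector_end)].vector_pos == t.vector_pos


def test_sites_never_on_vector_scaffold(lineage_e_records):
    records, refs, _ = lineage_e_records
    sites, _, _ = call_integration_sites(records, refs, CallerConfig.profile("multiplex"))
    assert sites and all(s.scaffold != refs.vector_name for s in sites)


def test_order_invariance(lineage_e_records):
    records, refs, _ = lineage_e_records
    config = CallerConfig.profile("multiplex")
    baseline, _, _ = call_integration_sites(records, refs, config)
    shuffled = records[:]
    random.Random(5).shuffle(shuffled)
    shuffled_sites, _, _ = call_integration_sites(shuffled, refs, config)
    assert [
        (s.scaffold, s.genome_pos, s.vector_pos, s.vector_end, s.support)
        for s in baseline
    ] == [
        (s.scaffold, s.genome_pos, s.vector_pos, s.vector_end, s.support)
        for s in shuffled_sites
    ]
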