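"""Simulator self-consistency: valid SAM, determinism, recoverable truth."""

from __future__ import annotations

import numpy as np
import pytest

from clonesite.alignment import clip_lengths, query_span, reference_span
from clonesite.caller import CallerConfig, call_integration_sites, extract_split_evidence
from clonesite.errors import ConfigurationError, PlacementError
from clonesite.simulate import (
    PRESET_NAMES,
    IntegrationTruth,
    SimConfig,
    make_reference,
    make_study_reference,
    preset,
    simulate_sam,
    study_samples,
    write_fasta,
)


def test_make_reference_shapes(tmp_path):
    sequences, refs = make_reference(2, 50_000, 8_000, seed=7)
    assert set(sequences) == {"scaffold_1", "scaffold_2", "vector"}
    assert len(sequences["vector"]) == 8_000
    assert refs.vector_length == 8_000 and len(refs.scaffold_names) == 2
    path = tmp_path / "ref.fasta"
    write_fasta(sequences, path)
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    assert [r.id for r in records] == ["scaffold_1", "scaffold_2", "vector"]


def test_make_reference_deterministic():
    a, _ = make_reference(2, 50_000, 8_000, seed=7)
    b, _ = make_reference(2, 50_000, 8_000, seed=7)
    c, _ = make_reference(2, 50_000, 8_000, seed=8)
    assert a == b and a != c


def test_make_reference_rejects_degenerate_arguments():
    with pytest.raises(ConfigurationError):
        make_reference(0, 50_000, 8_000, seed=1)
    with pytest.raises(ConfigurationError):
        make_reference(1, 10, 8_000, seed=1)


@pytest.fixture(scope="module")
def small_sim():
    sequences, refs = make_study_reference(5)
    truths = [IntegrationTruth("scaffold_1", 20_000, "right", 7_850)]
    config = SimConfig(support_per_junction=20, dup_rate=0.0, seed=5, sample="t")
    return simulate_sam(truths, config, refs, sequences=sequences), refs


def test_fixed_seed_gives_identical_bytes():
    sequences, refs = make_study_reference(5)
    truths, config = preset("lineage_A")
    a = simulate_sam(truths, config.replace(seed=5), refs, sequences=sequences)
    b = simulate_sam(truths, config.replace(seed=5), refs, sequences=sequences)
    assert a.sam_text() == b.sam_text()
    c = simulate_sam(truths, config.replace(seed=6), refs, sequences=sequences)
    assert a.sam_text() != c.sam_text()


def test_emitted_sam_is_internally_consistent(small_sim):
    result, refs = small_sim
    read_len = 100
    for record in result.iter_records():  # parse errors would raise here
        if record.is_unmapped:
            continue
        assert 1 <= record.pos <= refs.length(record.refname)
        assert record.pos + reference_span(record.cigar) - 1 <= refs.length(record.refname)
        assert query_span(record.cigar) == read_len
        for sa in record.sa_entries:
            # complementary split: this record's clipped bases are exactly
            # the partner alignment's aligned bases, and vice versa
            left, right = clip_lengths(record.cigar)
            sa_left, sa_right = clip_lengths(sa.cigar)
            sa_aligned = query_span(sa.cigar) - sa_left - sa_right
            assert left + right == sa_aligned
            assert query_span(sa.cigar) == read_len


def test_planted_support_is_exact(small_sim):
    result, refs = small_sim
    config = CallerConfig.profile("multiplex")
    qnames = set()
    for record in result.iter_records():
        ev = extract_split_evidence(record, refs, config)
        if ev is not None:
            assert (ev.genome_part.refname, ev.genome_junction) == ("scaffold_1", 20_000)
            qnames.add(ev.qname)
    assert len(qnames) == 20


def test_duplicates_flagged_and_not_counted():
    sequences, refs = make_study_reference(5)
    truths = [IntegrationTruth("scaffold_1", 20_000, "right", 7_850)]
    config = SimConfig(support_per_junction=10, dup_rate=0.5, seed=5, sample="t")
    result = simulate_sam(truths, config, refs, sequences=sequences)
    records = list(result.iter_records())
    assert any(r.is_duplicate for r in records)
    sites, _, _ = call_integration_sites(records, refs, CallerConfig.profile("multiplex"))
    assert len(sites) == 1 and sites[0].support == 10


def test_low_mapq_decoys_are_filtered_out():
    sequences, refs = make_study_reference(5)
    config = SimConfig(
        support_per_junction=10, dup_rate=0.0, n_decoys=5, decoy_mapq=10,
        decoy_support=10, seed=5, sample="t",
    )
    truths = [IntegrationTruth("scaffold_1", 20_000, "right", 7_850)]
    result = simulate_sam(truths, config, refs, sequences=sequences)
    sites, _, _ = call_integration_sites(
        result.iter_records(), refs, CallerConfig.profile("multiplex")
    )
    assert {(s.scaffold, s.genome_pos) for s in sites} == {("scaffold_1", 20_000)}


def test_suppressed_sa_junction_yields_no_site():
    sequences, refs = make_study_reference(5)
    truths = [
        IntegrationTruth("scaffold_1", 20_000, "right", 7_850),
        IntegrationTruth("scaffold_2", 20_000, "left", 150, suppress_sa=True),
    ]
    config = SimConfig(support_per_junction=10, dup_rate=0.0, seed=5, sample="t")
    result = simulate_sam(truths, config, refs, sequences=sequences)
    sites, _, _ = call_integration_sites(
        result.iter_records(), refs, CallerConfig.profile("multiplex")
    )
    assert {s.scaffold for s in sites} == {"scaffold_1"}


def test_capture_decay_depth_profile():
    """Flank coverage is non-increasing (in expectation) away from the junction."""
    sequences, refs = make_study_reference(5)
    truths = [IntegrationTruth("scaffold_1", 20_000, "right", 7_850)]
    config = SimConfig(
        support_per_junction=0, background_pairs_per_junction=2_000,
        vector_only_pairs=0, genome_only_pairs=0, unmapped_pairs=0,
        dup_rate=0.0, seed=5, sample="t",
    )
    result = simulate_sam(truths, config, refs, sequences=sequences)
    starts = [
        r.pos - 20_000
        for r in result.iter_records()
        if not r.is_unmapped and r.refname == "scaffold_1"
    ]
    window = 200
    counts = np.histogram(starts, bins=np.arange(0, 1_400, window))[0]
    assert counts[0] > counts[-1]
    assert all(np.diff(counts.astype(float)) <= counts.max() * 0.15)  # noise margin


def test_placement_errors():
    sequences, refs = make_study_reference(5)
    config = SimConfig(seed=1)
    with pytest.raises(PlacementError):  # too close to the scaffold edge
        simulate_sam(
            [IntegrationTruth("scaffold_1", 50, "right", 7_850)], config, refs
        )
    with pytest.raises(PlacementError):  # vector_pos contradicts vector_end
        simulate_sam(
            [IntegrationTruth("scaffold_1", 20_000, "right", 150)], config, refs
        )
    with pytest.raises(PlacementError):  # unknown scaffold
        simulate_sam(
            [IntegrationTruth("scaffold_99", 20_000, "right", 7_850)], config, refs
        )


# --- presets ----------------------------------------------------------------


def test_preset_shapes():
    truths, config = preset("sh87")
    assert len(truths) == 6 and config.read_len == 250
    assert len({t.scaffold for t in truths}) == 3
    truths, _ = preset("lineage_A")
    assert len(truths) == 2
    assert {t.vector_end for t in truths} == {"left", "right"}
    assert abs(truths[1].genome_pos - truths[0].genome_pos) == 30
    truths, _ = preset("lineage_E")
    assert len({t.scaffold for t in truths}) == 3
    for name in ("lineage_B", "lineage_D"):
        truths, _ = preset(name)
        assert len(truths) == 1
    with pytest.raises(ConfigurationError):
        preset("lineage_Z")


def test_study_samples_layout():
    samples = study_samples(1)
    assert len(samples) == 32
    assert {s[0] for s in samples} == {"A", "B", "C", "D", "E"}
    # the duplicate sample shares truths with its source but not its seed
    truths_a1, config_a1 = samples["A-1"]
    truths_dup, config_dup = samples["A-1D"]
    assert [t.genome_pos for t in truths_a1] == [t.genome_pos for t in truths_dup]
    assert config_a1.seed != config_dup.seed
    # study irregularities are planted
    assert len(samples["A-2"][0]) == 3
    assert any(t.support == 3 for t in samples["E-1"][0])
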