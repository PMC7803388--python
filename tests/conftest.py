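"""Shared fixtures: a small study reference and simulated samples.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import pytest

from clonesite.caller import CallerConfig, call_integration_sites
from clonesite.clonality import SampleSiteSet
from clonesite.simulate import (
    make_study_reference,
    preset,
    simulate_sam,
    study_samples,
)

SEED = 20260929


@pytest.fixture(scope="session")
def study_reference():
    """Sequences + ReferenceSet shared by all preset-based fixtures."""
    return make_study_reference(SEED)


@pytest.fixture(scope="session")
def sh87_sim(study_reference):
    sequences, refs = study_reference
    truths, config = preset("sh87")
    return simulate_sam(truths, config.replace(seed=SEED), refs, sequences=sequences)


@pytest.fixture(scope="session")
def study_site_sets(study_reference):
    """Called site sets for all 32 multiplexed study samples."""
    sequences, refs = study_reference
    config = CallerConfig.profile("multiplex")
    site_sets = {}
    for sample_id, (truths, sim_config) in study_samples(SEED).items():
        result = simulate_sam(truths, sim_config, refs, sequences=sequences)
        sites, _, _ = call_integration_sites(
            result.iter_records(), refs, config, sample=sample_id
        )
        site_sets[sample_id] = SampleSiteSet.from_sites(sample_id, sites)
    return site_sets
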