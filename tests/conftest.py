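import logging

import pytest

import ithimmune as it

logging.getLogger("ithimmune").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: planted gradients, cells and subtypes."""
    return it.simulate_cohort(it.SimConfig(seed=0))


@pytest.fixture(scope="session")
def normal_samples(cohort):
    return [s for s, g in cohort.truth.sample_group.items() if g == "NORMAL"]


@pytest.fixture(scope="session")
def pipeline_result(cohort, normal_samples):
    """Full pipeline run on the default cohort (shared across tests)."""
    return it.run_pipeline(
        cohort.expression,
        cohort.mutations,
        cohort.pathways,
        cohort.cell_markers,
        normal_samples,
        clinical=cohort.clinical,
        metabolic=cohort.metabolic,
        consensus_iters=500,
        seed=2024,
    )
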