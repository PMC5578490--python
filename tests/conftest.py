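import dataclasses

import pytest

from atacdiff.synthetic_data import (
    SimulationConfig,
    generate_genome,
    plant_regulatory_landscape,
    simulate_expression,
    simulate_tracks,
)

# a scaled-down landscape that keeps all structural features of the default
# study conditions but runs in well under a second per stage
SMALL = SimulationConfig(
    genome_length=600_000,
    n_chroms=2,
    n_peaks={"shared": 10, "cancer_only": 10, "normal_only": 5},
    events_per_sample=200_000,
    n_genes=40,
    seed=11,
)


@pytest.fixture(scope="session")
def small_config():
    return dataclasses.replace(SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(genome, truth, tracks, groups, fpkm, perturb) at the small scale."""
    genome = generate_genome(small_config)
    genome, truth = plant_regulatory_landscape(genome, small_config)
    tracks, groups = simulate_tracks(truth)
    fpkm, perturb = simulate_expression(truth)
    return genome, truth, tracks, groups, fpkm, perturb
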