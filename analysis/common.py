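"""Shared setup for the numbered analysis drivers.

Every driver regenerates the same default synthetic study deterministically
from one seed (regeneration is cheaper than parsing the multi-million-line
cleavage BEDs back in), then computes and writes its own stage tables under
results/.
"""

import os

from atacdiff.synthetic_data import (
    SimulationConfig,
    generate_genome,
    plant_regulatory_landscape,
    simulate_expression,
    simulate_tracks,
)

SEED = 1
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")


def results_path(name: str) -> str:
    os.makedirs(RESULTS, exist_ok=True)
    return os.path.join(RESULTS, name)


def default_dataset():
    """(config, genome, truth, tracks, groups, fpkm, perturb) at default scale."""
    config = SimulationConfig(seed=SEED)
    genome = generate_genome(config)
    genome, truth = plant_regulatory_landscape(genome, config)
    tracks, groups = simulate_tracks(truth)
    fpkm, perturb = simulate_expression(truth)
    return config, genome, truth, tracks, groups, fpkm, perturb
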