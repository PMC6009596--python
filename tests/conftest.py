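import numpy as np
import pytest

from polyasm import (DEFAULT_MOTIF, SimulationConfig, digest_sequence,
                     make_draft_with_chimeras, simulate_truth)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def truth_and_draft(default_config):
    """Default toy tetraploid with 5 planted chimeras (seed 1)."""
    truth = simulate_truth(default_config)
    draft, truth = make_draft_with_chimeras(truth, default_config)
    return truth, draft


@pytest.fixture(scope="session")
def genome_maps(truth_and_draft):
    truth, _ = truth_and_draft
    return [digest_sequence(s, DEFAULT_MOTIF, n)
            for n, s in sorted(truth.chromosomes.items())]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
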