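import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local oracle helpers

from venomforge import seqsim


@pytest.fixture(scope="session")
def small_config() -> seqsim.SimulationConfig:
    """A small but structurally complete two-species simulation."""
    return seqsim.SimulationConfig(
        seed=7,
        n_nontoxins=8,
        toxin_families=(
            seqsim.ToxinFamilySpec("3FTx", 2, 3, 2.5, n_codons=90),
            seqsim.ToxinFamilySpec("SVMPIII", 1, 2, 2.0, n_codons=150),
        ),
        n_read_pairs=2000,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return seqsim.simulate_transcriptomes(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
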