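import numpy as np
import pytest
from hypothesis import settings

from forksense import AnalysisConfig, GenomeSequence, SimulationSpec, simulate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_genome():
    """Two short chromosomes with known composition."""
    return GenomeSequence(
        {
            "chrI": "ACGT" * 2500,  # uniform 50% GC, 10 kb
            "chrII": "AT" * 2500 + "GC" * 2500,  # 0% then 100% GC, 10 kb
        }
    )


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale simulation: 2 x 100 kb, light peak load, fast to generate."""
    return SimulationSpec(
        n_chromosomes=2,
        chromosome_length_bp=100_000,
        n_peaks={
            "pfh1_wt": 40,
            "cdc20_wt": 30,
            "cdc20_depleted": 32,
            "gh2a_wt": 15,
            "gh2a_depleted": 35,
        },
        seed=7,
    )


@pytest.fixture(scope="session")
def study(small_spec):
    return simulate_study(small_spec)


@pytest.fixture
def fast_config():
    return AnalysisConfig(n_permutations=50, seed=11)
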