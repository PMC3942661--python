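import numpy as np
import pytest

from tissueqc.core import ReadPair
from tissueqc.sim import SimulationConfig, simulate_experiment


def make_pair(
    rid="r1",
    bases1="ACGT" * 25,
    quals1=None,
    bases2=None,
    quals2=None,
    qual=37,
):
    bases2 = bases2 if bases2 is not None else bases1
    quals1 = quals1 if quals1 is not None else np.full(len(bases1), qual)
    quals2 = quals2 if quals2 is not None else np.full(len(bases2), qual)
    return ReadPair(rid, bases1, quals1, bases2, quals2)


@pytest.fixture(scope="session")
def small_config():
    """Compact study configuration used by read-level tests."""
    return SimulationConfig(
        n_genes=20,
        library_size=800,
        contamination=(0.02, 0.02, 0.02, 0.02),
        groups=("WT", "WT", "KD", "KD"),
        cdna_input=(4.0, 6.0, 4.0, 6.0),
        frac_five_prime_lowqual=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)
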