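import numpy as np
import pytest

from prodiff import generate_random_regular, reference_constellation, run_simulation
from prodiff.experiments import run_batch


@pytest.fixture(scope="session")
def reference_batch():
    """100 reference-constellation runs shared across acceptance checks."""
    return run_batch(reference_constellation(), reps=100, seed=101)


@pytest.fixture(scope="session")
def reference_record():
    """One completed reference run with recorded production probabilities."""
    net = generate_random_regular(24, 6, rng_seed=7)
    return run_simulation(reference_constellation(), net=net, rng_seed=7, record_probs=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
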