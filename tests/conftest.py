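import logging

import numpy as np
import pytest

from vertpattern.simulate import GeneratorConfig, generate_cohort

# silence the per-side disagreement warnings the generator provokes on purpose
logging.getLogger("vertpattern.columns").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-subject default-parameter cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_subjects=400, seed=2024))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
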