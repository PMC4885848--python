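import numpy as np
import pytest

import perceptlearn as pl


@pytest.fixture(scope="session")
def default_sequence():
    return pl.generate_sequence(seed=123)


@pytest.fixture(scope="session")
def simulated_subject(default_sequence):
    """One synthetic observer at the default (full-model) parameters."""
    params = pl.ObserverParams()
    records = pl.simulate_observer(default_sequence, params, rng_seed=42)
    return default_sequence, records, params
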