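import numpy as np
import pytest

import robustbmi as rb


@pytest.fixture(scope="session")
def small_corpus():
    """One stable day, 40 trials, 16 electrodes — fast shared fixture."""
    corpus, tuning = rb.generate_corpus(
        1, 40, n_electrodes=16, seed=7, drift=rb.DriftProcess.none())
    return corpus, tuning


@pytest.fixture(scope="session")
def drifting_corpus():
    """Five drifting days, 30 trials each, 16 electrodes."""
    corpus, tuning = rb.generate_corpus(5, 30, n_electrodes=16, seed=11)
    return corpus, tuning


@pytest.fixture(scope="session")
def tiny_mrnn():
    """A small random MRNN with nonzero readout, for numeric oracles."""
    params = rb.init_mrnn(4, 4, 3, 2, rb.InitSpec(seed=3), tau=100.0,
                          dt=20.0)
    rng = np.random.default_rng(5)
    vec = params.to_vector()
    return params.with_vector(vec + rng.normal(scale=0.1, size=vec.size))
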