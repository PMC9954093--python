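import logging

import numpy as np
import pytest

from placeqtl import simulate

logging.getLogger("placeqtl").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """A small default-condition dataset shared by read-only tests."""
    # seed chosen so the sampled gestational-age / disease-group correlation
    # stays below the |0.9| collinearity cutoff (it frequently crosses it at
    # n = 57 under the study's confounding; crossing is handled, but this
    # fixture exercises the canonical 23-column design)
    cfg = simulate.SimConfig(n_samples=57, n_genes=60, n_snps=240, seed=13)
    return simulate.simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
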