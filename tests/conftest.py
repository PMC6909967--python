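import logging

import numpy as np
import pytest

from circboost.synthetic import SynthConfig, generate

logging.getLogger("circboost").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale bundle with strong planted structure (fast to process)."""
    cfg = SynthConfig(
        n_circ=30,
        n_disease=12,
        n_blocks=3,
        seq_len=(60, 100),
        n_sites=10,
        within_block_assoc_prob=0.35,
        between_block_assoc_prob=0.01,
        seed=7,
    )
    return generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
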