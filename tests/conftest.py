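import numpy as np
import pytest

from spenhancer import ModelConfig, MotifSpec, SyntheticConfig, generate


@pytest.fixture(scope="session")
def tiny_planted_config():
    """Small, strongly planted two-offset dataset: easy detection task."""
    return SyntheticConfig(
        n_strong=30,
        n_weak=30,
        n_non=60,
        length=40,
        motifs=[
            MotifSpec(
                positions=(8, 24),
                motif="GATAAG",
                p_strong=1.0,
                p_weak=1.0,
                p_background=0.0,
            )
        ],
        seed=75,
    )


@pytest.fixture(scope="session")
def tiny_planted_dataset(tiny_planted_config):
    return generate(tiny_planted_config)


@pytest.fixture()
def small_model_config():
    """Desk-scale hyperparameters for fast training tests."""
    return ModelConfig(Q=8, pLSTMSize=4, pDropoutRatio=0.2, pBatchSize=16,
                       max_epochs=3, seed=75)


@pytest.fixture()
def rng():
    return np.random.default_rng(75)
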