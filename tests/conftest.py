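import numpy as np
import pytest

import radlung as rl


@pytest.fixture(scope="session")
def swine_config():
    return rl.PhantomConfig.swine()


@pytest.fixture(scope="session")
def swine_subject(swine_config):
    """One fully generated default swine subject (shared across tests)."""
    return rl.generate_subject(swine_config, [1, 1], subject_id="swine01")


@pytest.fixture(scope="session")
def swine_table(swine_subject):
    """Measured per-bin table for the shared swine subject."""
    return rl.measure_subject(swine_subject)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_grid(values=None, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0)):
    if values is None:
        values = np.zeros(shape)
    return rl.ImageGrid(values, spacing, (0.0, 0.0, 0.0))


def small_mask(values, spacing=(1.0, 1.0, 1.0)):
    return rl.BinaryMask(values, spacing, (0.0, 0.0, 0.0))
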