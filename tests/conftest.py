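import numpy as np
import pytest

from abdm.simulate import GeneratingConfig, generate_study


@pytest.fixture(scope="session")
def reference_study():
    """One study at the reference design (120 persons x 70 items, c = 0.35)."""
    return generate_study(GeneratingConfig(seed=20240917))


@pytest.fixture(scope="session")
def small_study():
    """A cheap 20-item x 30-person study for sampler/JML unit tests."""
    cfg = GeneratingConfig(n_persons=30, n_items=20, seed=11)
    return generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
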