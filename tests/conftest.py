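import numpy as np
import pytest

from pawstrike import ClipRenderSpec, aged_distribution, render_dataset


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale render geometry used throughout the unit tests."""
    return ClipRenderSpec(height=32, width=32)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """120 aged-distribution clips at 32x32, rendered once per session."""
    return render_dataset(aged_distribution(), 120, small_spec, seed=2024)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
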