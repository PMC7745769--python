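import numpy as np
import pytest

from xhybscan.pipeline import analyze_dataset
from xhybscan.synthetic import InjectedSpec, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort used by most integration tests."""
    return SyntheticConfig(
        seed=7,
        n_samples=150,
        n_background_probes=250,
        injected=(
            InjectedSpec(18),
            InjectedSpec(25),
            InjectedSpec(14),
            InjectedSpec(20, oob_switch=True),
            InjectedSpec(28, oob_switch=True),
            InjectedSpec(16, edits=1, edit_offset=10),
            InjectedSpec(30, infinium_type="II"),
            InjectedSpec(11),
        ),
        n_loci=60,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_analysis(small_dataset):
    return analyze_dataset(small_dataset)


@pytest.fixture(scope="session")
def default_dataset():
    """The full-size study conditions: 400 samples, 5000 + 30 probes."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    return analyze_dataset(default_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
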