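import pytest

from mirsm import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced generator configuration for fast unit tests."""
    return SynthConfig(
        n_samples=48,
        n_mirnas=24,
        n_mrnas=60,
        n_modules=2,
        module_mirna_size=6,
        module_mrna_size=10,
        n_background_tf_edges=20,
        n_background_ppi_edges=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate_dataset(small_cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The standard study conditions: 72 samples, 2 implanted modules."""
    return generate_dataset(seed=1)
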