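import pytest

import deerflux as dx


@pytest.fixture(scope="session")
def study_config():
    """Shipped study-like generator configuration."""
    return dx.default_config(seed=42)


@pytest.fixture(scope="session")
def study_ds(study_config):
    """One synthetic survey drawn under study-like noise."""
    return dx.generate(study_config, seed=42)


@pytest.fixture(scope="session")
def noise_free_ds():
    """Degenerate survey whose pipeline output equals the analytic truth."""
    return dx.generate(dx.noise_free_config(), seed=0)
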