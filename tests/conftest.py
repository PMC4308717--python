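import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """Scaled-down panel for fast unit tests (the default config is exercised
    by the acceptance suite)."""
    from xconstraint.simulate import SimConfig

    return SimConfig(
        n_genes=400, n_samples=8,
        n_junctions=200, n_junction_samples=10,
        n_isoform_genes=40, n_isoform_samples=8,
        n_bins=2000, n_mark_genes=60,
    )
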