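import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("det")

from pharmaca import AnalysisConfig, GeneratorConfig, generate_session


@pytest.fixture(scope="session")
def fast_config():
    """Desk-scale analysis config: reduced shuffle/repeat counts."""
    return AnalysisConfig.fast(score_null_iters=2000, ccg_null_iters=500,
                               subset_repeats=10)


@pytest.fixture(scope="session")
def stationary_session():
    """Full-length saline session with no planted effects (40 neurons)."""
    cfg = GeneratorConfig(n_neurons=40, seed=42, frac_excited=0.0,
                          frac_inhibited=0.0)
    session, truth = generate_session(cfg, "saline")
    return session, truth


@pytest.fixture(scope="session")
def drug_session():
    """Full-length drug session with planted excited/inhibited subpopulations."""
    cfg = GeneratorConfig(n_neurons=40, seed=7)
    session, truth = generate_session(cfg, "pitolisant")
    return session, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
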