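import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from rmstswitch import ScenarioConfig  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def example1_config():
    """Colorectal-cancer trial design: exponential medians 6.0/6.4 months,
    instant accrual, 26-month duration, RMST at 12 months, 80% preserved
    fraction of the control RMST, 5% control censoring, alpha 0.005."""
    return ScenarioConfig(
        n=232, m1=6.0, m2=6.4, shape=1.0, Ta=0.0, Te=26.0, tau=12.0,
        f1=0.8, censoring_rate=0.05, one_sided_alpha=0.005,
        n_simulations=1000, seed=71,
    )


@pytest.fixture
def study_config():
    """Simulation-study design: median 1 (control), 3-year accrual in a
    5-year trial, RMST horizon 5, 20% control censoring, margin preserving
    half the control-vs-placebo DRMST (placebo median 0.5), alpha 0.025."""
    return ScenarioConfig(
        n=158, m1=1.0, m2=1.1, shape=1.0, Ta=3.0, Te=5.0, tau=5.0,
        f2=0.5, m0=0.5, censoring_rate=0.2, one_sided_alpha=0.025,
        n_simulations=1000, seed=72,
    )
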