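import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from workhrr.synth import ScenarioConfig, simulate_cohort, simulate_outcomes_metric_level
from workhrr.types import IbiSeries


@pytest.fixture(scope="session")
def default_cfg() -> ScenarioConfig:
    return ScenarioConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    return simulate_cohort(default_cfg)


@pytest.fixture(scope="session")
def metric_outcomes(default_cfg, cohort):
    return simulate_outcomes_metric_level(cohort, default_cfg)


def make_series(ibi_ms, error_flag=None, worker_id="w", day=0, start_s=0.0):
    """Beat series from a list of intervals, timestamps accumulated from them."""
    ibi = np.asarray(ibi_ms, dtype=float)
    t = start_s + np.cumsum(ibi) / 1000.0
    if error_flag is None:
        error_flag = np.zeros(len(ibi), dtype=bool)
    return IbiSeries(worker_id, day, t, ibi, np.asarray(error_flag, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
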