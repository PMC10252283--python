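import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mircervix as mc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def complete_sample() -> mc.SampleAssay:
    return mc.SampleAssay(
        sample_id="S1",
        diagnosis="NILM",
        hpv_status="NEG",
        ct_mir21=24.0,
        ct_mir29b=26.0,
        ct_mir145=25.0,
        ct_mir451a=23.0,
        ct_mir1246=27.0,
        ct_mir1290=29.0,
        ct_actb=28.0,
        ct_celmir39=17.5,
    )


@pytest.fixture
def small_cohort() -> mc.Cohort:
    """Fast study-shaped cohort: 40 + 40 samples, no injected QC failures."""
    params = mc.default_params(seed=11).replace(n_nilm=40, n_hsil=40, qc_fail_rate=0.0)
    return mc.simulate_cohort(params)


@pytest.fixture
def fast_config() -> mc.PipelineConfig:
    return mc.PipelineConfig(
        forest=mc.ForestConfig(n_trees=30),
        cv=mc.CVConfig(k=5),
        seed=11,
    )


@pytest.fixture
def separable_toy():
    """1-D separable predictor matrix: only chi1 carries signal."""
    rng = np.random.default_rng(5)
    n = 40
    X = np.ones((n, 9))
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    X[: n // 2, 0] = 0.1
    X[n // 2 :, 0] = 10.0
    return X, y
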