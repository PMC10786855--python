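import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import micc

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def danish_mf():
    """Mean-field Danish calibration: N=1e6, f0/N=1e-5, rN=b=9.24e-3, R0=4.2e-5."""
    return micc.danish_meanfield()


@pytest.fixture(scope="session")
def danish_st():
    """Stochastic Danish calibration (rN = b/0.977)."""
    return micc.danish_stochastic()


@pytest.fixture(scope="session")
def small_params():
    """Small system where stochastic effects are visible: N=200, f0=2, rN=0.5/yr."""
    return micc.ModelParams(N=200, r=0.5 / 200, f0=2)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    """20k event-driven trajectories of the small system to age 4 (rNt up to 2)."""
    return micc.simulate_cohort(
        small_params, None, n=20_000, master_seed=20240, t_max=4.0, sample_deaths=False
    )


@pytest.fixture(scope="session")
def danish_cohort_meanrate():
    """2000 trajectories at the mean-field rate (rN=b), deaths ignored, to age 150."""
    params, scale = micc.danish_meanfield()
    return micc.simulate_cohort(
        params, scale, n=2000, master_seed=4242, t_max=150.0, sample_deaths=False
    )


def bootstrap_se(values: np.ndarray, stat, n_boot: int = 200, seed: int = 0) -> float:
    """Trajectory-resampling bootstrap standard error of a statistic."""
    rng = np.random.default_rng(seed)
    n = len(values)
    reps = [stat(values[rng.integers(0, n, n)]) for _ in range(n_boot)]
    return float(np.std(reps, ddof=1))
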