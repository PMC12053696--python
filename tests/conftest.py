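import warnings

import pytest

from octoclock import (
    MCMCConfig,
    SimulationConfig,
    fit_ordinal,
    generate_codex,
    generate_cohort,
)
from octoclock.simulate import simulate_cumulative_frame

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_codex():
    """3 systems x 2 diseases, 3 severity levels each."""
    return generate_codex(3, 2, 3, seed=0)


@pytest.fixture(scope="session")
def small_cohort(small_codex):
    cfg = SimulationConfig(n_individuals=150, n_visits=3, seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(cfg, small_codex)


@pytest.fixture(scope="session")
def small_fit():
    """A converged cumulative-monotonic fit on model-generated data, reused
    across prediction and evaluation tests."""
    frame, truth = simulate_cumulative_frame(
        150, 3, [3, 2], thresholds=[-1.0, 0.5, 2.0], b_max=[1.2, 0.8],
        beta_time=0.1, sigma_u=0.5, seed=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_ordinal(frame, sampler=MCMCConfig(seed=2, n_warmup=500, n_draws=700))
    return frame, truth, fit


def assert_close(a, b, tol, msg=""):
    assert abs(float(a) - float(b)) <= tol, f"{msg}: |{a} - {b}| > {tol}"
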