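import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PCSM_LANDMARKS = {5.0: 0.999, 10.0: 0.990, 15.0: 0.978}


def brute_force_km(times, events):
    """Independent product-limit computation by explicit looping.

    Returns a list of (time, n_risk, n_event, survival, greenwood_variance)
    over distinct event times.  At tied times all subjects with time >= t are
    at risk (events before censorings).
    """
    times = list(map(float, times))
    events = list(map(int, events))
    distinct = sorted({t for t, e in zip(times, events) if e == 1})
    s = 1.0
    gw = 0.0
    rows = []
    for t in distinct:
        n = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        s *= 1.0 - d / n
        if n > d:
            gw += d / (n * (n - d))
            var = s * s * gw
        else:
            var = 0.0  # survival hit zero
        rows.append((t, n, d, s, var))
    return rows


def random_cohort(rng, n_max=30):
    """Small random cohort with heavy ties and censoring."""
    n = int(rng.integers(1, n_max + 1))
    times = rng.integers(1, 11, size=n) / 2.0  # grid of 0.5 -> many ties
    events = rng.integers(0, 2, size=n)
    return times, events


@pytest.fixture(scope="session")
def pcsm_hazard():
    from survscale import calibrate_piecewise_hazard

    return calibrate_piecewise_hazard(PCSM_LANDMARKS)


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort shared by read-only tests."""
    from survscale import default_study_spec, generate_cohort

    return generate_cohort(default_study_spec(n_subjects=920, seed=20230409))
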