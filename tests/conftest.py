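import numpy as np
import pandas as pd
import pytest

import pradelts as pt


@pytest.fixture(scope="session")
def study_calendar():
    """The full biannual design: October 1993 .. May 2014."""
    return pt.occasion_calendar("1993-10", "2014-05")


@pytest.fixture(scope="session")
def short_calendar():
    """A 6-occasion slice of the biannual design."""
    return pt.occasion_calendar("1993-10", "1996-05")


@pytest.fixture(scope="session")
def sim_constant(short_calendar):
    """Constant-rate population on a small biannual calendar."""
    cfg = pt.SimulationConfig(seed=42, n_initial=400, calendar=short_calendar, p=0.6)
    return pt.simulate_population(cfg)


@pytest.fixture(scope="session")
def sim_monthly():
    """Delta t = 1 simulation where monthly and interval scales coincide."""
    cal = pt.regular_calendar("2000-01", 10)
    cfg = pt.SimulationConfig(
        seed=7, n_initial=2000, calendar=cal, phi_m=0.8, f_m=0.2, p=0.6
    )
    return pt.simulate_population(cfg)


@pytest.fixture
def tiny_records():
    return pd.DataFrame(
        {
            "animal_id": ["a1", "a1", "a1", "a2", "a2", "a3", "a4"],
            "session": ["1993-10", "1993-10", "1994-10", "1993-10", "1994-10",
                        "1994-05", "1994-05"],
            "sex": ["F", "F", "F", "F", "F", "M", "M"],
            "age": ["adult"] * 7,
        }
    )


def random_rates(rng, T):
    """Random valid parameter set on the interval scale."""
    p = rng.uniform(0.15, 0.9, T)
    Phi = rng.uniform(0.2, 0.95, T - 1)
    gamma = rng.uniform(0.2, 0.95, T - 1)
    return p, Phi, gamma
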