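import dataclasses

import pytest

import filicann as fc


@pytest.fixture(scope="session")
def real_set():
    return fc.real_parameters()


@pytest.fixture(scope="session")
def illustrative_set():
    return fc.illustrative_parameters()


@pytest.fixture
def short_season(real_set):
    fp, lh = real_set
    return fp, dataclasses.replace(lh, season_units=14)


def weak_crowding_scenario(seed: int):
    """A seeded random parameter set in the weak-within-step-nonlinearity
    regime: plentiful heterospecific prey, long searches, short activity
    windows, so one female's consumption barely perturbs encounter shares and
    the mean-field recursion is the exact expectation of the individual-based
    model up to O(1/N)."""
    fp, lh = fc.random_parameters(seed, ranges={
        "y": (150.0, 400.0),
        "b": (0.2, 1.5),
        "tau_s": (30.0, 90.0),
        "tau_a": (20.0, 120.0),
        "tau_b": (20.0, 120.0),
    })
    lh = dataclasses.replace(lh, activity_minutes_per_unit=600)
    return fp, lh
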