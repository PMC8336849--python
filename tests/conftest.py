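import numpy as np
import pytest

import ageflux as af


@pytest.fixture
def type_b_profile() -> af.AgeProfile:
    """11-age profile with the reconstructed type-B survival ladder and
    constant (type-A) activity 1."""
    return af.make_profile("B", "A", max_age=10)


@pytest.fixture
def pulse100() -> af.PulsePolicy:
    return af.PulsePolicy(100.0)


def random_profile(rng: np.random.Generator, max_age: int | None = None,
                   type_a_activity: bool = False) -> af.AgeProfile:
    """A random valid profile for property tests."""
    if max_age is None:
        max_age = int(rng.integers(2, 11))
    survival = rng.uniform(0.0, 1.0, max_age)
    if type_a_activity:
        activity = np.ones(max_age + 1)
    else:
        activity = rng.uniform(0.0, 2.0, max_age + 1)
    return af.AgeProfile(survival, activity)


def random_schedule(rng: np.random.Generator) -> af.DemandSchedule:
    kind = rng.integers(0, 3)
    if kind == 0:
        return af.ConstantDemand(float(rng.uniform(0, 400)))
    if kind == 1:
        return af.RotationDemand(
            [float(rng.uniform(0, 200)), float(rng.uniform(0, 200))],
            [int(rng.integers(1, 10)), int(rng.integers(1, 10))])
    return af.LogisticDemand(float(rng.uniform(0, 400)),
                             float(rng.uniform(0, 5)),
                             float(rng.uniform(0.05, 0.5)))
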