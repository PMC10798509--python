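import numpy as np
import pytest

from reflexgait.collect import CollectionSchedule, velocity_sweep
from reflexgait.surrogate import SurrogateConfig, SurrogateEvaluator, make_two_level_dataset


@pytest.fixture(scope="session")
def two_level_dataset():
    """18 x 9 two-CoT-level toy dataset for one control parameter."""
    return make_two_level_dataset()


@pytest.fixture(scope="session")
def surrogate():
    return SurrogateEvaluator()


@pytest.fixture(scope="session")
def quiet_surrogate():
    """Noise-free surrogate for deterministic value checks."""
    return SurrogateEvaluator(SurrogateConfig(noise_v=0.0, noise_cot=0.0))


@pytest.fixture(scope="session")
def reduced_schedule():
    """Desk-scale schedule: 3 target velocities, G=30, lambda=10."""
    return CollectionSchedule(
        thread_a_start=1.3,
        thread_a_end=1.4,
        thread_b_start=1.2,
        thread_b_end=1.2,
        step=0.1,
        G=30,
        lam=10,
        mu=4,
    )


@pytest.fixture(scope="session")
def swept(reduced_schedule, surrogate):
    """One shared reduced collection sweep (dataset, log)."""
    return velocity_sweep(reduced_schedule, surrogate, seed=11)
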