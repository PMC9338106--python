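import numpy as np
import pytest

from endpointmotion import (
    Geometry,
    NoiseModel,
    ResponseModel,
    build_schedule,
    simulate_session,
)


@pytest.fixture(scope="session")
def geom():
    return Geometry()


@pytest.fixture(scope="session")
def resp():
    return ResponseModel()


@pytest.fixture(scope="session")
def silent_noise():
    return NoiseModel.silent()


@pytest.fixture(scope="session")
def small_schedule():
    """One repetition of every condition cell (12 trials)."""
    return build_schedule(reps_per_cell=1, n_blocks=1, seed=11)


@pytest.fixture(scope="session")
def clean_session(small_schedule, resp, silent_noise, geom):
    """A 12-trial noise-free session (one trial per condition cell)."""
    return simulate_session(small_schedule, resp, silent_noise, geom, seed=5)


@pytest.fixture(scope="session")
def full_session(resp, geom):
    """One participant's full 600-trial session with default noise."""
    schedule = build_schedule(reps_per_cell=25, n_blocks=2, seed=3)
    return simulate_session(schedule, resp, NoiseModel(), geom, seed=3)
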