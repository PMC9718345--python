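import numpy as np
import pytest

from thermoresp import (BreathingProfile, SensorModel, SessionSchedule,
                        simulate_session)


@pytest.fixture
def default_profile():
    return BreathingProfile()


@pytest.fixture
def quiet_sensor():
    """Noise-free sensor with no transport delay: extrema timing is exact
    up to the 100 ms first-order lag."""
    return SensorModel(noise_sd=0.0, transport_delay_per_kg=0.0,
                       transport_delay_intercept=0.0)


@pytest.fixture
def ideal_sensor():
    """Identity sensor: no lag, no mixing, no delay, no noise."""
    return SensorModel(time_constant=0.0, noise_sd=0.0,
                       transport_delay_per_kg=0.0,
                       mixing_tau_by_position={-5: 0.0, 0: 0.0, 5: 0.0})


@pytest.fixture
def empty_schedule():
    return SessionSchedule(blocks=[])


def make_session(seed=0, duration=300.0, noise_sd=0.0, chest_noise_sd=0.0,
                 profile=None, sensor=None, schedule=None, **kwargs):
    """Short stimulus-free session used across the suite."""
    profile = profile or BreathingProfile()
    sensor = sensor or SensorModel(noise_sd=noise_sd,
                                   transport_delay_per_kg=0.0)
    schedule = schedule if schedule is not None else SessionSchedule(blocks=[])
    kwargs.setdefault("include_lick", False)
    return simulate_session(profile=profile, sensor=sensor, schedule=schedule,
                            duration=duration, seed=seed,
                            chest_noise_sd=chest_noise_sd, **kwargs)


@pytest.fixture
def session_factory():
    return make_session


def random_smooth_trace(rng, n=1500, fs=100.0):
    """Band-limited random trace resembling a respiration recording."""
    from thermoresp import SampledTrace
    from thermoresp.respiration import moving_average

    x = rng.normal(size=n)
    x = moving_average(x, 25)
    x = x / (np.std(x) or 1.0)
    x += 0.1 * rng.normal(size=n)
    return SampledTrace(x, fs=fs, label="random")
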