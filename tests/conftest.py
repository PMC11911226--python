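import numpy as np
import pytest

from ergocap import AthleteProfile, ErgometerTrace, WheelGeometry

GEOMETRY = WheelGeometry(wheel_radius=0.31, rim_radius=0.26)
UNIT_GEOMETRY = WheelGeometry(wheel_radius=0.30, rim_radius=0.30)


@pytest.fixture
def geometry():
    return GEOMETRY


@pytest.fixture
def profile():
    """Whole-group mean athlete: 67 kg, 13 kg chair, 26 y."""
    return AthleteProfile(mass_user=67.0, mass_wheelchair=13.0, sex="male",
                          age=26.0, sport="tennis")


def make_trace(torque_left, torque_right, velocity_left, velocity_right,
               sample_rate=100.0, geometry=GEOMETRY):
    n = len(torque_left)
    return ErgometerTrace(
        time=np.arange(n) / sample_rate,
        torque_left=np.asarray(torque_left, float),
        torque_right=np.asarray(torque_right, float),
        velocity_left=np.asarray(velocity_left, float),
        velocity_right=np.asarray(velocity_right, float),
        geometry=geometry,
        sample_rate=sample_rate,
    )


def const_trace(duration_s, torque, velocity, sample_rate=100.0, geometry=GEOMETRY):
    """Trace with identical constant torque/velocity on both sides."""
    n = int(round(duration_s * sample_rate)) + 1
    ones = np.ones(n)
    return make_trace(torque * ones, torque * ones, velocity * ones,
                      velocity * ones, sample_rate, geometry)


def random_active_trace(rng, duration_s, sample_rate=10.0, geometry=GEOMETRY):
    """Random trace whose power never drops low enough to trigger start trim."""
    n = int(round(duration_s * sample_rate)) + 1
    return make_trace(
        rng.uniform(5.0, 15.0, n), rng.uniform(5.0, 15.0, n),
        rng.uniform(1.0, 3.0, n), rng.uniform(1.0, 3.0, n),
        sample_rate, geometry,
    )


def brute_force_max_window_mean(values, window_samples):
    """Independent exhaustive scan over every fully populated window."""
    best = -np.inf
    for start in range(len(values) - window_samples + 1):
        best = max(best, float(np.mean(values[start:start + window_samples])))
    return best
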