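import numpy as np
import pytest

from radarvitals import (RadarConfig, SceneDescription, TargetTruth,
                         VitalProfile, simulate_cube, two_tone)


@pytest.fixture(scope="session")
def config():
    return RadarConfig()


@pytest.fixture(scope="session")
def benchmark_signal():
    """The two-tone benchmark: A1=1, A2=0.8, f1=1.05, f2=1.25 Hz, NS=200, fs=20."""
    return two_tone(1.0, 0.8, 1.05, 1.25, 20.0, 200)


@pytest.fixture(scope="session")
def static_target_cube(config):
    """Noiseless cube with one motionless reflector at 0.9 m."""
    vital = VitalProfile(respiration_amplitude=0.0, heartbeat_amplitude=0.0)
    scene = SceneDescription(targets=(TargetTruth(0.9, 0.0, vital),),
                             snr_db=None, duration=6.4, seed=0)
    return simulate_cube(scene, config)


@pytest.fixture(scope="session")
def vital_cube(config):
    """Noiseless single-subject cube: 0.9 m, breathing and heartbeat."""
    scene = SceneDescription(targets=(TargetTruth(0.9, 0.0, VitalProfile()),),
                             snr_db=None, duration=6.4, seed=0)
    return simulate_cube(scene, config)


def synthetic_phase(rate=20.0, n=512, heartbeat_hz=1.233, seed=None,
                    snr_db=None, respiration=True):
    """Chest-phase fixture: respiration + harmonics + heartbeat in radians."""
    from scipy.constants import c as c0
    from radarvitals import add_awgn, chest_displacement
    t = np.arange(n) / rate
    vital = VitalProfile(
        heartbeat_frequency=heartbeat_hz,
        respiration_amplitude=4e-3 if respiration else 0.0)
    lam = c0 / 77e9
    phase = 4 * np.pi / lam * chest_displacement(vital, t)
    phase -= phase.mean()
    if snr_db is not None:
        phase = add_awgn(phase, snr_db, 0 if seed is None else seed)
    return phase
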