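import numpy as np
import pytest

from divetrack.config import RunConfig
from divetrack.pipeline import process_bundle
from divetrack.simulate import TripConfig, simulate_trip


@pytest.fixture(scope="session")
def default_trip():
    """A 6 h default-noise simulated trip (seed 42): (bundle, truth)."""
    return simulate_trip(TripConfig(seed=42, duration_h=6.0))


@pytest.fixture(scope="session")
def default_result(default_trip):
    bundle, _ = default_trip
    return process_bundle(bundle, RunConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_trip():
    """A 3 h noise-free, fallback-speed trip (seed 7): (bundle, truth)."""
    return simulate_trip(TripConfig.noiseless(seed=7, duration_h=3.0))


@pytest.fixture(scope="session")
def noiseless_result(noiseless_trip):
    bundle, _ = noiseless_trip
    return process_bundle(bundle, RunConfig(seed=1))


def rotation_body_from_ned(heading, pitch, roll):
    """Independent forward oracle: R such that v_body = R @ v_ned.

    Built directly from the yaw-pitch-roll elemental matrices, kept separate
    from the package's inverse formulas on purpose.
    """
    ch, sh = np.cos(heading), np.sin(heading)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cr, sr = np.cos(roll), np.sin(roll)
    Rz = np.array([[ch, -sh, 0], [sh, ch, 0], [0, 0, 1]])
    Ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    Rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    return (Rz @ Ry @ Rx).T


def earth_field_ned(declination_deg, inclination_deg, intensity=60.0):
    D, I = np.radians(declination_deg), np.radians(inclination_deg)
    return intensity * np.array([np.cos(I) * np.cos(D), np.cos(I) * np.sin(D), np.sin(I)])
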