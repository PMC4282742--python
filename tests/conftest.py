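import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import footkin as fk

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def template():
    return fk.make_template()


@pytest.fixture(scope="session")
def static_series(template):
    return fk.generate_static_trial(template, n_frames=50)


@pytest.fixture(scope="session")
def calib(static_series):
    return fk.compute_static_reference(static_series)


@pytest.fixture(scope="session")
def walking(template):
    """Noise-free 3-cycle walking trial with ground truth."""
    spec = fk.SimSpec(n_cycles=3, noise_mm=0.0, seed=1)
    return fk.generate_trial(template, spec)


def random_rotation(rng, max_tilt_deg=60.0):
    """Rigid rotation with bounded tilt of the vertical axis (upright capture)."""
    from scipy.spatial.transform import Rotation

    yaw = Rotation.from_euler("y", rng.uniform(0, 360), degrees=True)
    ax = np.array([np.cos(a := rng.uniform(0, 2 * np.pi)), 0.0, np.sin(a)])
    tilt = Rotation.from_rotvec(np.radians(rng.uniform(0, max_tilt_deg)) * ax)
    return (tilt * yaw).as_matrix()


def transform_series(series, r=None, t=None):
    out = series.copy()
    if r is not None:
        out.data = out.data @ np.asarray(r).T
    if t is not None:
        out.data = out.data + np.asarray(t, dtype=float)
    return out
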