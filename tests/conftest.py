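import numpy as np
import pytest

import equigait as eg
from equigait.datamodel import SensorLocation, SensorRecording


def make_static_recording(location="ST", quat=None, fs=64.0, duration=3.0):
    """Constant-attitude, gravity-only recording (a sensor lying still)."""
    loc = SensorLocation.from_key(location) if isinstance(location, str) else location
    T = int(duration * fs)
    if quat is None:
        quat = np.array([1.0, 0.0, 0.0, 0.0])
    quat = np.tile(np.asarray(quat, float) / np.linalg.norm(quat), (T, 1))
    from scipy.spatial.transform import Rotation

    # measured specific force of a static sensor: gravity in sensor frame
    g_sensor = Rotation.from_quat(quat[0], scalar_first=True).inv().apply(
        [0.0, 0.0, eg.GRAVITY])
    acc = np.tile(g_sensor, (T, 1))
    gyro = np.zeros((T, 3))
    return SensorRecording(location=loc, fs=fs, acc=acc, gyro=gyro, quat=quat)


@pytest.fixture(scope="session")
def canter_template():
    return eg.default_template("canter")


@pytest.fixture(scope="session")
def small_session(canter_template):
    """One quiet canter session with sternum, sacrum and a cannon sensor."""
    tpl = canter_template.subset(("ST", "SA", "FC_L"))
    spec = eg.HerdSpec(n_horses=2, passages_per_run=1, duration_s=8.0, seed=11)
    return eg.generate_session(tpl, eg.FatigueEffect.null(), spec, 0, "before")


@pytest.fixture(scope="session")
def full_session(canter_template):
    """All nine sensors, one passage (used for channel accounting)."""
    spec = eg.HerdSpec(n_horses=2, passages_per_run=1, duration_s=6.0, seed=5)
    return eg.generate_session(canter_template, eg.FatigueEffect.null(), spec, 0, "before")
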