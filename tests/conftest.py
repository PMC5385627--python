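import numpy as np
import pytest

import imuturn as it


@pytest.fixture(scope="session")
def suite():
    """Canned scenario fixtures, one render per test session."""
    return it.scenario_suite(seed=1)


@pytest.fixture(scope="session")
def clean(suite):
    return suite["clean"]


def make_track(yaw_deg, fs=100.0):
    """AttitudeTrack carrying a prescribed unwrapped yaw (identity rotations).

    Only the fields consumed by segmentation are meaningful; rotation
    matrices are identity placeholders.
    """
    yaw = np.asarray(yaw_deg, dtype=float)
    n = len(yaw)
    t = np.arange(n) / fs
    return it.AttitudeTrack(
        t=t,
        R=np.tile(np.eye(3), (n, 1, 1)),
        roll_deg=np.zeros(n),
        pitch_deg=np.zeros(n),
        yaw_deg=((yaw + 180.0) % 360.0) - 180.0,
        yaw_unwrapped_deg=yaw,
        gimbal_flags=np.zeros(n, dtype=bool),
    )


def piecewise_linear_yaw(values, seg_samples=100):
    """Linear interpolation through the given yaw way-points."""
    parts = [
        np.linspace(a, b, seg_samples, endpoint=False)
        for a, b in zip(values, values[1:])
    ]
    return np.concatenate(parts + [[values[-1]]])
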