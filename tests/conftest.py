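import numpy as np
import pytest

from icpcv import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_params():
    return synth.GazeModelParams()


@pytest.fixture
def centered_eye():
    return synth.EyeGeometry(
        eye_center=(40.0, 25.0),
        eye_half_width=20.0,
        eye_half_height=8.0,
        pupil_center=(40.0, 25.0),
        pupil_radius=5.0,
    )


def random_eye_geometry(rng, eyebrow=False):
    """A random in-bounds eye geometry with the pupil inside the ellipse."""
    hw = rng.uniform(15.0, 25.0)
    hh = rng.uniform(6.0, 10.0)
    cx = rng.uniform(hw + 12, hw + 30)
    cy = rng.uniform(hh + 25, hh + 40)
    dx = rng.uniform(-0.4, 0.4) * hw
    dy = rng.uniform(-0.3, 0.3) * hh
    return synth.EyeGeometry(
        eye_center=(cx, cy),
        eye_half_width=hw,
        eye_half_height=hh,
        pupil_center=(cx + dx, cy + dy),
        pupil_radius=rng.uniform(3.0, 6.0),
        eyebrow=eyebrow,
    )


def random_observation(rng, spread=100.0):
    """Random landmark set for feature-algebra checks."""

    def pt(center):
        return np.asarray(center) + rng.uniform(-spread, spread, 2)

    left = synth.EyePoints(pt((250, 200)), pt((300, 200)), pt((240, 200)))
    right = synth.EyePoints(pt((390, 200)), pt((340, 200)), pt((400, 200)))
    return synth.GazeObservation(left, right, np.array([500.0, 400.0]), 0)
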