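"""Shared fixtures: scenes, eye parameters, and small simulated sessions."""

from __future__ import annotations

import numpy as np
import pytest

from purkinjeye.eye_model import GazeTarget, load_eye_parameters
from purkinjeye.scene import SceneConfig, load_scene
from purkinjeye.synthetic import ProtocolSpec, make_session, make_subject


@pytest.fixture(scope="session")
def scene():
    return load_scene()


@pytest.fixture(scope="session")
def eye_params():
    return load_eye_parameters()


@pytest.fixture(scope="session")
def small_angle_scene():
    """A near-paraxial layout: LED and camera within ~1 deg of the axis."""
    return SceneConfig(
        led_position=[0.0, -8.0, 500.0],
        camera_pinhole=[0.0, 8.0, 500.0],
        camera_axis=[0.0, -8.0, -500.0],
        focal_length_px=10000.0,
        sensor_size=(4000, 3000),
    )


@pytest.fixture(scope="session")
def short_protocol(scene):
    """Three-depth protocol with short dwell: fast sessions for unit tests."""
    targets = tuple(GazeTarget(1.0 / a, 0.0315) for a in (4.0, 2.5, 1.0))
    return ProtocolSpec(targets=targets, dwell_s=0.6, frame_rate_hz=50.0)


@pytest.fixture(scope="session")
def session_df(scene, short_protocol):
    """One noisy subject session over the short protocol (90 frames)."""
    subject = make_subject(7, feature_noise_px=0.3, blink_prob=0.0)
    return make_session(subject, short_protocol, scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
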