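"""Shared fixtures: a small, fast synthetic scene for module tests."""

from __future__ import annotations

import numpy as np
import pytest

from footclear import SceneSpec, render_scene


def small_spec(**overrides) -> SceneSpec:
    """A 270x480 scene that renders in well under a second.

    Geometry is the default scene scaled down ~4x; noise off unless a
    test asks for it.
    """
    base = dict(
        seed=11,
        frame_height=270,
        frame_width=480,
        n_frames=48,
        n_lead=4,
        sole_length_px=48.0,
        shoe_height_px=22.0,
        start_col=60.0,
        end_col=420.0,
        h_a=28.0,
        h_b=8.0,
        ground=((0.0, 230.0), (479.0, 230.0)),
        laser_col=240.0,
        laser_upper_row=100.0,
        laser_sep_px=60.0,
        laser_radius=3.0,
        laser_n_frames=10,
        noise_sigma=0.0,
    )
    base.update(overrides)
    return SceneSpec(**base)


@pytest.fixture(scope="session")
def quiet_scene():
    """Noise-free small scene rendered once per session."""
    return render_scene(small_spec())


@pytest.fixture(scope="session")
def noisy_scene():
    """The same scene with sensor noise."""
    return render_scene(small_spec(noise_sigma=5.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
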