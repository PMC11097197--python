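"""Shared fixtures and synthetic-field helpers."""

import numpy as np
import pytest

from hemoveloc import make_triphasic_waveform, render_particle_images
from hemoveloc.types import BLOOD_MIMICKING_FLUID, VelocityField2D


@pytest.fixture(scope="session")
def waveform():
    """Default triphasic CFA inflow waveform (1 Hz, 9.6/2.3 mL)."""
    return make_triphasic_waveform()


@pytest.fixture(scope="session")
def fluid():
    return BLOOD_MIMICKING_FLUID


def uniform_field(vx_cm: float, vy_cm: float = 0.0,
                  extent=(12.8, 6.4), spacing: float = 0.1) -> VelocityField2D:
    """Constant-velocity field covering a small rectangular domain."""
    x = np.arange(0.0, extent[0], spacing)
    y = np.arange(0.0, extent[1], spacing)
    shape = (1, y.size, x.size)
    return VelocityField2D(
        x=x, y=y, t=np.array([0.0]),
        vx=np.full(shape, vx_cm), vy=np.full(shape, vy_cm),
        mask=np.ones((y.size, x.size), dtype=bool),
    )


def render_uniform(vx_cm: float, vy_cm: float = 0.0, *, n_frames=2,
                   noise_sd=0.0, seed=3, pixel_size=0.05, frame_rate=2000.0,
                   seeding_density=None) -> tuple:
    """Render a uniform-translation particle sequence; returns
    (sequence, true displacement in px per frame interval)."""
    field = uniform_field(vx_cm, vy_cm)
    seq = render_particle_images(
        field, seeding_density=seeding_density, pixel_size=pixel_size,
        frame_rate=frame_rate, n_frames=n_frames, noise_sd=noise_sd, seed=seed,
    )
    dpx = vx_cm * 10.0 / frame_rate / pixel_size
    dpy = vy_cm * 10.0 / frame_rate / pixel_size
    return seq, (dpx, dpy)
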