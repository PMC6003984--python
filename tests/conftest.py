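"""Shared fixtures: a reduced ring system that keeps the physics intact
while making forward simulation and reconstruction fast enough for unit
tests (fewer elements, shorter record, smaller ring)."""

import numpy as np
import pytest

from ringpact import ArrayGeometry, TransducerModel


@pytest.fixture(scope="session")
def small_geometry():
    return ArrayGeometry(
        ring_radius=30.0,
        n_elements=128,
        element_height=5.0,
        element_pitch=1.35,
    )


@pytest.fixture(scope="session")
def small_transducer():
    return TransducerModel(record_length=40.0)


@pytest.fixture(scope="session")
def full_geometry():
    return ArrayGeometry()


@pytest.fixture(scope="session")
def full_transducer():
    return TransducerModel()


def _textured(seed, shape):
    from scipy import ndimage as _ndi

    rng = np.random.default_rng(seed)
    img = _ndi.gaussian_filter(rng.random(shape), 1.5)
    return (img - img.min()) / (img.max() - img.min())


@pytest.fixture(scope="session")
def compression_study():
    """Compression phantom with a 0.5-compliance stiff inclusion, 20 s at
    10 Hz, non-rigidly registered and triangulated once per session (the
    demons registration of 200 frames dominates the cost).

    Returns (sequence, inclusion mask, displacement result, triangle grid).
    """
    from ringpact import (
        generate_dynamic_frames,
        register_nonrigid,
        stable_triangulation,
    )

    base = _textured(3, (160, 160))
    ny, nx = base.shape
    stiff = np.ones_like(base)
    yy, xx = np.mgrid[0:ny, 0:nx]
    incl = (yy - 80) ** 2 + (xx - 80) ** 2 <= 30**2
    stiff[incl] = 0.5
    seq = generate_dynamic_frames(
        base, "compression", frequency=0.25, amplitude=0.015,
        n_frames=200, frame_rate=10.0, stiffness=stiff, seed=0,
    )
    disp = register_nonrigid(seq)
    grid = stable_triangulation(seq, disp, seed=0)
    return seq, incl, disp, grid
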