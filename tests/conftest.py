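import numpy as np
import pytest

import rootspeckle as rs


@pytest.fixture(scope="session")
def geom():
    """Default bench geometry: 633 nm, sin(theta)=1, 3 mm gauge, 0.5 s frames."""
    return rs.OpticalGeometry()


@pytest.fixture(scope="session")
def presets():
    return rs.load_presets()


@pytest.fixture(scope="session")
def speckle_pair():
    """Two independent 64x64 speckle fields reused across rendering tests."""
    return (
        rs.generate_speckle_field((64, 64), speckle_size_px=2.0, seed=11),
        rs.generate_speckle_field((64, 64), speckle_size_px=2.0, seed=12),
    )


@pytest.fixture(scope="session")
def render_stack(geom, speckle_pair):
    """Render a frame stack whose object phase follows ``phi_true`` exactly."""

    def _render(phi_true, noise_sd=0.0, seed=None, fields=None):
        fa, fb = fields if fields is not None else speckle_pair
        t = np.arange(len(phi_true)) * geom.dt_s
        elong = rs.ElongationTrace(
            times_s=t, x_nm=rs.phase_to_elongation(np.asarray(phi_true), geom)
        )
        return rs.render_frame_stack(elong, fa, fb, geom, noise_sd=noise_sd, seed=seed)

    return _render
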