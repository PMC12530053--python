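import numpy as np
import pytest

from sed3d.azimuthal import RingConfig
from sed3d.datamodel import AcquisitionMeta, FrameStack
from sed3d.reconstruct import OrientationField
from sed3d.tiltalign import PlaneTransform, TiltSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ring():
    return RingConfig()


@pytest.fixture
def small_meta():
    return AcquisitionMeta(
        tilt_deg=0.0, step_nm=100.0, recip_pixel_inv_A=0.009, camera_shape=(64, 64)
    )


def gaussian_spot(shape, row, col, amplitude=100.0, sigma=1.5):
    """A single Gaussian peak on an otherwise empty detector."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((yy - row) ** 2 + (xx - col) ** 2) / (2 * sigma**2))


def spot_pattern_at_azimuth(shape, phi_deg, radius_px, antipodal=True, **kw):
    """Pattern with Gaussian spot(s) on the ring at the given azimuth."""
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    phi = np.radians(phi_deg)
    img = gaussian_spot(shape, cy - radius_px * np.sin(phi), cx + radius_px * np.cos(phi), **kw)
    if antipodal:
        img = img + gaussian_spot(
            shape, cy + radius_px * np.sin(phi), cx - radius_px * np.cos(phi), **kw
        )
    return img


def identity_series(maps, tilts):
    """Wrap co-registered azimuth maps as an aligned tilt series."""
    return TiltSeries(
        maps=list(maps),
        transforms=[PlaneTransform.identity() for _ in maps],
        tilts_deg=list(tilts),
    )


def uniform_field(shape, axis):
    """An OrientationField with the same axis at every pixel."""
    axis = np.asarray(axis, dtype=float)
    axes = np.broadcast_to(axis, (*shape, 3)).copy()
    return OrientationField(
        axis=axes,
        residual=np.zeros(shape),
        valid=np.ones(shape, bool),
        degenerate=np.zeros(shape, bool),
    )


from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("sed3d", derandomize=True, deadline=None)
_hyp_settings.load_profile("sed3d")
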