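import numpy as np
import pytest

from conedrift import capture as cap
from conedrift import mosaic as mz
from conedrift import optics as op

LATTICE_SPACING_ARCSEC = 35.69  # spacing of the sparse reference mosaic


@pytest.fixture(scope="session")
def raster() -> op.RasterSpec:
    return op.RasterSpec()


@pytest.fixture(scope="session")
def lattice_mosaic() -> mz.ConeMosaic:
    """Perfect triangular lattice, tessellated."""
    pts = mz.triangular_lattice(LATTICE_SPACING_ARCSEC / 3600.0, 0.15)
    return mz.tessellate(mz.ConeMosaic(pts))


@pytest.fixture(scope="session")
def jittered_mosaic() -> mz.ConeMosaic:
    """~200-cone jittered lattice (uniform jitter, 8% of spacing)."""
    rng = np.random.default_rng(42)
    s = LATTICE_SPACING_ARCSEC / 3600.0
    pts = mz.triangular_lattice(s, 0.07)
    pts = pts + rng.uniform(-0.08 * s, 0.08 * s, pts.shape)
    return mz.tessellate(mz.ConeMosaic(pts))


@pytest.fixture(scope="session")
def lattice_apertures(lattice_mosaic) -> cap.ApertureMap:
    return cap.build_apertures(lattice_mosaic)


def interior_mask(mosaic: mz.ConeMosaic, margin_deg: float) -> np.ndarray:
    """Cones farther than ``margin_deg`` from the mosaic's outer radius."""
    r = np.linalg.norm(mosaic.positions, axis=1)
    return r <= r.max() - margin_deg


def gaussian_spot(sigma_arcsec: float, pitch_arcsec: float,
                  half_extent_arcsec: float) -> np.ndarray:
    """Smooth radially symmetric activation image (test stimulus)."""
    ax = np.arange(-half_extent_arcsec, half_extent_arcsec + pitch_arcsec / 2,
                   pitch_arcsec)
    X, Y = np.meshgrid(ax, ax)
    return np.exp(-(X**2 + Y**2) / (2 * sigma_arcsec**2))
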