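"""AOSLO raster geometry, Tumbling-E stimulus construction, and the
diffraction-limited retinal image.

The scanning raster spans a 0.85 x 0.85 degree field sampled with 512 x 512
pixels at 27 Hz (pixel pitch ~5.98 arcsec, frame period ~37 ms).  Stimuli
are dark (OFF-contrast) Tumbling-E optotypes drawn into the raster by
switching the scanning laser off; stimulus size is quantified by the stroke
width, one fifth of the letter height.  The retinal image is the nominal
stimulus convolved with the eye's diffraction-limited point spread function
(Airy pattern for 788-nm light and a 7-mm pupil; first zero at
1.22 lambda/D ~ 28.3 arcsec).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from scipy.special import j1

from .errors import DegenerateInputError, ResolutionError

ORIENTATIONS = ("right", "up", "left", "down")  # k*90 deg CCW from "right"


@dataclass(frozen=True)
class RasterSpec:
    """Scanner field geometry and timing."""

    field_deg: float = 0.85
    lines: int = 512
    pixels_per_line: int = 512
    frame_rate_hz: float = 27.0
    wavelength_nm: float = 788.0
    pupil_mm: float = 7.0

    @property
    def pixel_pitch_arcsec(self) -> float:
        return self.field_deg * 3600.0 / self.pixels_per_line

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate_hz

    @property
    def airy_first_zero_arcsec(self) -> float:
        theta = 1.22 * (self.wavelength_nm * 1e-9) / (self.pupil_mm * 1e-3)
        return theta * 180.0 / np.pi * 3600.0


@dataclass
class StimulusBitmap:
    """Rasterized stimulus: dark letter on a bright background.

    ``grid`` holds gray values on a ~10-bit scale (0..background); pixel
    pitch equals the raster pitch.  ``stroke_px`` is the stroke width in
    raster pixels (possibly fractional).
    """

    grid: np.ndarray
    stroke_px: float
    orientation: str
    pad: int
    background: float = 1000.0
    pixel_pitch_arcsec: float = 5.9765625

    @property
    def activation(self) -> np.ndarray:
        """OFF-contrast activation in [0, 1]: light decrement / background."""
        return (self.background - self.grid) / self.background


def _e_mask(xs: np.ndarray, ys: np.ndarray, stroke: float) -> np.ndarray:
    """Boolean mask of a right-opening E centered at the origin.

    The letter spans 5 x 5 stroke widths: a full-height spine on the left
    and three limbs (top, middle, bottom) of one stroke width each, with
    gaps equal to the stroke width.
    """
    h = 2.5 * stroke
    X, Y = np.meshgrid(xs, ys)
    inside = (np.abs(X) <= h) & (np.abs(Y) <= h)
    spine = inside & (X <= -h + stroke)
    limbs = inside & ((np.abs(Y) >= h - stroke) | (np.abs(Y) <= stroke / 2))
    return spine | limbs


def make_tumbling_e(stroke_arcsec: float, orientation: str,
                    raster: RasterSpec | None = None, *, oversample: int = 8,
                    pad: int = 8, background: float = 1000.0) -> StimulusBitmap:
    """Build a Tumbling-E bitmap on the raster grid.

    The letter is drawn on an ``oversample``-times finer nominal grid,
    blurred with a 5-pixel / sigma = 1 pixel Gaussian (sub-pixel edge
    placement), then block-averaged down to raster pitch.  ``pad`` raster
    pixels of background surround the letter so the blur never touches the
    border.
    """
    raster = raster or RasterSpec()
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    pitch = raster.pixel_pitch_arcsec
    if stroke_arcsec <= 0:
        raise ResolutionError("stroke must be positive")
    if stroke_arcsec < pitch / 10.0:
        raise ResolutionError(
            f"stroke {stroke_arcsec:.3g} arcsec below a tenth of the "
            f"{pitch:.3g} arcsec pixel pitch")

    fine = pitch / oversample
    half_px = int(np.ceil(2.5 * stroke_arcsec / pitch)) + pad
    n_fine = 2 * half_px * oversample
    coords = (np.arange(n_fine) - (n_fine - 1) / 2) * fine
    mask = _e_mask(coords, coords, stroke_arcsec).astype(float)
    # 5-px kernel, sigma = 1 px on the nominal (fine) grid
    blurred = ndimage.gaussian_filter(mask, sigma=1.0, truncate=2.0)
    coarse = blurred.reshape(2 * half_px, oversample,
                             2 * half_px, oversample).mean(axis=(1, 3))
    k = ORIENTATIONS.index(orientation)
    coarse = np.rot90(coarse, k)
    grid = background * (1.0 - coarse)
    return StimulusBitmap(np.clip(grid, 0.0, background),
                          stroke_px=stroke_arcsec / pitch,
                          orientation=orientation, pad=pad,
                          background=background, pixel_pitch_arcsec=pitch)


def diffraction_psf(raster: RasterSpec | None = None, *,
                    support_zeros: float = 8.0,
                    pitch_arcsec: float | None = None) -> np.ndarray:
    """Airy intensity pattern for a circular pupil, sampled at raster pitch
    and normalized to unit sum.

    Support extends to ``support_zeros`` times the first-zero radius; at
    the default 8 radii the truncated energy is < 0.5%.
    """
    raster = raster or RasterSpec()
    if support_zeros < 2.0:
        raise DegenerateInputError("PSF support must cover the second Airy ring")
    pitch = pitch_arcsec if pitch_arcsec is not None else raster.pixel_pitch_arcsec
    r0 = raster.airy_first_zero_arcsec
    half = int(np.ceil(support_zeros * r0 / pitch))
    ax = (np.arange(2 * half + 1) - half) * pitch
    X, Y = np.meshgrid(ax, ax)
    theta = np.hypot(X, Y) / 3600.0 * np.pi / 180.0  # rad
    x = np.pi * (raster.pupil_mm * 1e-3) * theta / (raster.wavelength_nm * 1e-9)
    with np.errstate(invalid="ignore", divide="ignore"):
        airy = (2.0 * j1(x) / x) ** 2
    airy[x == 0] = 1.0
    return airy / airy.sum()


def retinal_image(stim: np.ndarray | StimulusBitmap, psf: np.ndarray,
                  mode: str = "full") -> np.ndarray:
    """Linear convolution of the stimulus with the PSF (zero padding).

    Pass an activation array (OFF-contrast, [0, 1]) or a StimulusBitmap
    (its ``activation`` is used).  With a unit-sum PSF and ``mode='full'``
    the total OFF-contrast energy is conserved exactly.
    """
    arr = stim.activation if isinstance(stim, StimulusBitmap) else np.asarray(stim, float)
    if arr.size == 0 or psf.size == 0:
        raise DegenerateInputError("empty array")
    return signal.fftconvolve(arr, psf, mode=mode)


def trim_activation(activation: np.ndarray, keep: float = 0.999) -> np.ndarray:
    """Crop an activation image to the central box holding ``keep`` of its
    energy (symmetric trim; speeds up aperture capture with negligible
    loss)."""
    act = np.asarray(activation, float)
    total = act.sum()
    if total <= 0:
        return act
    rows = act.sum(axis=1).cumsum() / total
    cols = act.sum(axis=0).cumsum() / total
    eps = (1.0 - keep) / 2.0
    r0, r1 = np.searchsorted(rows, eps), np.searchsorted(rows, 1 - eps) + 1
    c0, c1 = np.searchsorted(cols, eps), np.searchsorted(cols, 1 - eps) + 1
    # keep the crop centered so the image center stays the stimulus center
    H, W = act.shape
    dr, dc = min(r0, H - r1), min(c0, W - c1)
    return act[dr:H - dr or None, dc:W - dc or None]


def sweep_time(rows_covered: int, raster: RasterSpec | None = None) -> float:
    """Time (ms) for the scanner to sweep ``rows_covered`` raster lines.

    Line flyback is ignored: the frame period is divided uniformly across
    the raster lines.
    """
    raster = raster or RasterSpec()
    if not 0 <= rows_covered <= raster.lines:
        raise DegenerateInputError("rows_covered outside [0, lines]")
    return rows_covered / raster.lines * raster.frame_period_ms


def verify_delivery(intended: np.ndarray, delivered: np.ndarray,
                    threshold: float = 0.8) -> tuple[float, bool]:
    """Normalized peak cross-correlation between intended and delivered
    stimulus, for flagging distorted or missing presentations.

    Both arrays are mean-subtracted; the score is the correlation peak over
    all spatial shifts, 1.0 for an exact (possibly shifted) copy.  Returns
    ``(score, passed)`` with ``passed = score >= threshold``.
    """
    a = np.asarray(intended, float)
    b = np.asarray(delivered, float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("empty array")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0, False
    score = float(signal.fftconvolve(a, b[::-1, ::-1], mode="full").max() / denom)
    score = min(score, 1.0)
    return score, score >= threshold
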