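"""Light capture by cone apertures over drift trajectories.

Each cone is assigned a Gaussian light-acceptance aperture whose diameter
(full width at half maximum by convention) is 48% of the local intercone
distance.  For every stimulus-on video frame the diffraction-limited
retinal image of the stimulus is placed at that frame's retinal position
and multiplied with the aperture array; per-cone captures are accumulated
over frames and normalized by the total light captured during the trial.
Cones capturing more than 1% of the trial total are classified as *seeing
cones* — the smallest detectable contrast increment.

Aggregate statistics: per-cone stimulation counts across trials (seeing
heatmap), the fraction of engaged cones forming a habitual core (seeing in
more than ``min_hits`` trials), and the isocontour area (ISOA) enclosing a
fixed fraction (68%) of stimulus landing points, whose centroid is the
average stimulus location on the retina.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .errors import CurationError, DegenerateInputError
from .mosaic import DEG2ARCSEC, ConeMosaic

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM / 2.3548
APERTURE_FRACTION = 0.48
SEEING_FRACTION = 0.01


@dataclass
class ApertureMap:
    """Per-cone Gaussian apertures (unit-integral weights)."""

    centers_deg: np.ndarray   # (n, 2)
    sigma_arcsec: np.ndarray  # (n,)
    fwhm_arcsec: np.ndarray   # (n,)


def build_apertures(mosaic: ConeMosaic, fraction: float = APERTURE_FRACTION,
                    convention: str = "fwhm") -> ApertureMap:
    """Gaussian aperture per cone with diameter = ``fraction`` x local ICD.

    ``convention`` selects how the quoted diameter maps onto the Gaussian:
    ``"fwhm"`` (literature convention for cone apertures) or ``"2sigma"``.
    """
    if not mosaic.tessellated:
        raise DegenerateInputError("mosaic has no per-cone ICD; tessellate first")
    icd = mosaic.icd
    diam = fraction * icd
    if convention == "fwhm":
        sigma = diam * FWHM_TO_SIGMA
    elif convention == "2sigma":
        sigma = diam / 2.0
    else:
        raise ValueError("convention must be 'fwhm' or '2sigma'")
    return ApertureMap(mosaic.positions.copy(), sigma, diam)


@dataclass
class ConeActivationMap:
    """Captured light per cone for one trial."""

    capture: np.ndarray        # raw per-cone capture (arbitrary units)
    fraction: np.ndarray       # capture / total capture, in [0, 1]
    seeing: np.ndarray         # fraction > seeing threshold
    total_capture: float
    per_frame: np.ndarray | None = None  # (n_frames, n_cones) optional

    @property
    def seeing_indices(self) -> np.ndarray:
        return np.flatnonzero(self.seeing)


def capture_frame(activation: np.ndarray, pitch_arcsec: float,
                  center_deg: tuple, apertures: ApertureMap,
                  out: np.ndarray | None = None,
                  support_sigmas: float = 4.0) -> np.ndarray:
    """Aperture-weighted capture of one placed retinal image.

    ``activation`` is the OFF-contrast retinal image (rows top to bottom);
    its center pixel sits at ``center_deg`` on the retina.  Per-cone
    capture adds into ``out`` (created if None).
    """
    H, W = activation.shape
    n = len(apertures.centers_deg)
    if out is None:
        out = np.zeros(n)
    cx = apertures.centers_deg[:, 0] * DEG2ARCSEC
    cy = apertures.centers_deg[:, 1] * DEG2ARCSEC
    ox, oy = center_deg[0] * DEG2ARCSEC, center_deg[1] * DEG2ARCSEC
    sig = apertures.sigma_arcsec
    smax = sig.max()
    half_w = (W - 1) / 2 * pitch_arcsec
    half_h = (H - 1) / 2 * pitch_arcsec
    margin = support_sigmas * smax
    near = ((np.abs(cx - ox) <= half_w + margin)
            & (np.abs(cy - oy) <= half_h + margin))
    idx = np.flatnonzero(near)
    if idx.size == 0:
        return out
    # continuous pixel coordinates of each cone center
    jc_all = (cx[idx] - ox) / pitch_arcsec + (W - 1) / 2
    ic_all = (H - 1) / 2 - (cy[idx] - oy) / pitch_arcsec
    # patch radius per cone; group cones by radius so an outlier aperture
    # does not inflate every patch
    r_all = np.ceil(support_sigmas * sig[idx] / pitch_arcsec).astype(int)
    for r in np.unique(r_all):
        grp = r_all == r
        gi = idx[grp]
        ic, jc = ic_all[grp], jc_all[grp]
        offs = np.arange(-r, r + 1)
        di, dj = np.meshgrid(offs, offs, indexing="ij")
        di, dj = di.ravel(), dj.ravel()
        ii = np.round(ic).astype(int)[:, None] + di[None, :]
        jj = np.round(jc).astype(int)[:, None] + dj[None, :]
        inb = (ii >= 0) & (ii < H) & (jj >= 0) & (jj < W)
        vals = activation[np.where(inb, ii, 0), np.where(inb, jj, 0)]
        dx = (jj - jc[:, None]) * pitch_arcsec
        dy = (ic[:, None] - ii) * pitch_arcsec
        s2 = sig[gi][:, None] ** 2
        w = np.exp(-(dx**2 + dy**2) / (2 * s2)) * pitch_arcsec**2 / (2 * np.pi * s2)
        np.add.at(out, gi, (vals * w * inb).sum(axis=1))
    return out


def capture_trial(activation: np.ndarray, pitch_arcsec: float,
                  apertures: ApertureMap, frame_positions_deg: np.ndarray,
                  frame_valid: np.ndarray | None = None,
                  seeing_threshold: float = SEEING_FRACTION,
                  keep_frames: bool = False,
                  support_sigmas: float = 4.0) -> ConeActivationMap:
    """Accumulate per-cone capture over the stimulus-on frames of a trial.

    ``frame_positions_deg`` holds the retinal position of the stimulus
    center for each stimulus-on frame (a single row for a one-frame,
    zero-slip presentation).  Fractions are normalized by the total light
    captured over the whole trial; seeing cones exceed the 1% rule.
    """
    frame_positions_deg = np.atleast_2d(np.asarray(frame_positions_deg, float))
    if frame_valid is not None and not np.all(frame_valid):
        raise CurationError("trace gap during a stimulus-on frame")
    n = len(apertures.centers_deg)
    total = np.zeros(n)
    per_frame = [] if keep_frames else None
    for pos in frame_positions_deg:
        f = capture_frame(activation, pitch_arcsec, tuple(pos), apertures,
                          support_sigmas=support_sigmas)
        if keep_frames:
            per_frame.append(f)
        total += f
    tot = float(total.sum())
    frac = total / tot if tot > 0 else np.zeros(n)
    return ConeActivationMap(
        capture=total, fraction=frac, seeing=frac > seeing_threshold,
        total_capture=tot,
        per_frame=np.array(per_frame) if keep_frames else None)


def seeing_heatmap(seeing_sets: list, n_cones: int) -> np.ndarray:
    """Count, per cone, the trials in which it was a seeing cone."""
    counts = np.zeros(n_cones, dtype=int)
    for s in seeing_sets:
        counts[np.asarray(s, dtype=int)] += 1
    return counts


def core_fraction(counts: np.ndarray, min_hits: int = 10) -> float:
    """Fraction of ever-engaged cones stimulated more than ``min_hits``
    times — the habitual core of the seeing region."""
    engaged = counts > 0
    if not engaged.any():
        return 0.0
    return float((counts > min_hits).sum() / engaged.sum())


@dataclass
class IsoaSummary:
    """Isocontour region of stimulus landing points."""

    centroid: tuple            # same units as the input points
    area: float                # units^2
    contained_fraction: float
    level: float               # KDE density threshold
    offset_to_cdc: float | None = None


def isoa(points: np.ndarray, mass: float = 0.68,
         cdc: tuple | None = None, grid_n: int = 200) -> IsoaSummary:
    """Kernel-density isocontour containing ``mass`` of the landing points.

    A Gaussian KDE (Silverman bandwidth) is evaluated at the sample points;
    the density level is the (1 - mass) quantile of those values, so the
    superlevel set contains the target fraction of points.  Region area and
    density-weighted centroid are measured on a regular grid.
    """
    pts = np.asarray(points, float)
    if len(pts) < 20:
        raise DegenerateInputError("need >= 20 landing points")
    if np.allclose(pts.std(axis=0), 0):
        warnings.warn("degenerate landing points: zero-area ISOA")
        c = tuple(pts[0])
        off = float(np.hypot(c[0] - cdc[0], c[1] - cdc[1])) if cdc else None
        return IsoaSummary(c, 0.0, 1.0, np.inf, off)
    kde = gaussian_kde(pts.T, bw_method="silverman")
    dens_at_pts = kde(pts.T)
    level = float(np.quantile(dens_at_pts, 1.0 - mass))
    contained = float(np.mean(dens_at_pts >= level))

    lo = pts.min(axis=0) - 3 * pts.std(axis=0)
    hi = pts.max(axis=0) + 3 * pts.std(axis=0)
    xs = np.linspace(lo[0], hi[0], grid_n)
    ys = np.linspace(lo[1], hi[1], grid_n)
    X, Y = np.meshgrid(xs, ys)
    D = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(X.shape)
    mask = D >= level
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    area = float(mask.sum() * cell)
    w = np.where(mask, D, 0.0)
    centroid = (float((w * X).sum() / w.sum()), float((w * Y).sum() / w.sum()))
    off = None
    if cdc is not None:
        off = float(np.hypot(centroid[0] - cdc[0], centroid[1] - cdc[1]))
    return IsoaSummary(centroid, area, contained, level, off)
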