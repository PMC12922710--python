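"""Cone-mosaic structure metrics.

The retinal sampling array is described by the coordinates of cone centers
(degrees of visual angle, origin at the raster center, x rightward, y
upward).  From a Voronoi tessellation of the centers we derive, per cone,
the bounded cell area and the intercone distance (ICD, the mean Euclidean
distance to Voronoi-adjacent cones).  Cone density maps average the cell
areas of the `k` cones nearest each map pixel; the cone density centroid
(CDC) is the density-weighted center of the connected region at >= 80% of
peak density and serves as the anatomical foveal center.  The Nyquist limit
of a quasi-hexagonal mosaic is the row-to-row spacing, N_c = ICD * sqrt(3)/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull, Delaunay, QhullError, Voronoi, cKDTree

from .errors import DegenerateInputError, OutOfDomainError, TessellationError

DEG2ARCSEC = 3600.0
SQRT3 = np.sqrt(3.0)


@dataclass
class ConeMosaic:
    """Cone centers plus per-cone Voronoi geometry.

    Attributes
    ----------
    positions : (n, 2) float array, degrees of visual angle.
    cell_areas : (n,) float array, deg^2; NaN for unbounded/edge cells.
    bounded : (n,) bool array; True where the Voronoi cell is finite and
        fully inside the convex hull of the mosaic (edge cells excluded
        from all area-based statistics).
    icd : (n,) float array, arcsec; mean distance to Voronoi neighbors.
    neighbors : list of index arrays (Voronoi adjacency).
    """

    positions: np.ndarray
    cell_areas: np.ndarray | None = None
    bounded: np.ndarray | None = None
    icd: np.ndarray | None = None
    neighbors: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise DegenerateInputError("cone positions must be an (n, 2) array")

    @property
    def n_cones(self) -> int:
        return len(self.positions)

    @property
    def tessellated(self) -> bool:
        return self.icd is not None


def read_cone_csv(path) -> ConeMosaic:
    """Read a cone-coordinate table (CSV with header ``x_deg,y_deg``)."""
    df = pd.read_csv(path)
    return ConeMosaic(df[["x_deg", "y_deg"]].to_numpy(dtype=float))


def write_cone_csv(mosaic: ConeMosaic, path) -> None:
    pd.DataFrame(mosaic.positions, columns=["x_deg", "y_deg"]).to_csv(path, index=False)


def _polygon_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def tessellate(mosaic: ConeMosaic) -> ConeMosaic:
    """Voronoi-tessellate the mosaic, filling cell areas, ICD, adjacency.

    Cells that are unbounded, or whose vertices extend outside the convex
    hull of the cone centers, are flagged ``bounded=False`` and carry
    ``cell_area = NaN``: boundary cells do not estimate local density.
    """
    pts = mosaic.positions
    if len(pts) < 7:
        raise DegenerateInputError(f"need >= 7 cones, got {len(pts)}")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    if np.min(d[:, 1]) <= 0:
        raise DegenerateInputError("duplicate cone positions")
    try:
        vor = Voronoi(pts)
        hull = Delaunay(pts)
    except QhullError as exc:  # collinear or otherwise degenerate
        raise TessellationError(str(exc)) from exc

    n = len(pts)
    areas = np.full(n, np.nan)
    bounded = np.zeros(n, dtype=bool)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue
        verts = vor.vertices[region]
        if np.all(hull.find_simplex(verts) >= 0):
            bounded[i] = True
            areas[i] = _polygon_area(verts)

    neighbors: list[list[int]] = [[] for _ in range(n)]
    for (a, b) in vor.ridge_points:
        neighbors[a].append(b)
        neighbors[b].append(a)
    neigh_arrays = [np.array(sorted(v), dtype=int) for v in neighbors]

    icd = np.full(n, np.nan)
    for i, nb in enumerate(neigh_arrays):
        if len(nb):
            icd[i] = np.mean(np.linalg.norm(pts[nb] - pts[i], axis=1)) * DEG2ARCSEC

    return ConeMosaic(pts, cell_areas=areas, bounded=bounded, icd=icd,
                      neighbors=neigh_arrays)


@dataclass
class DensityMap:
    """Cone density sampled on a regular grid (cones/deg^2)."""

    grid: np.ndarray          # (ny, nx), cones/deg^2
    x: np.ndarray             # (nx,) pixel-center x, degrees
    y: np.ndarray             # (ny,) pixel-center y, degrees
    pixel_pitch: float        # arcsec per grid pixel
    cdc: tuple | None = None  # (x, y) degrees
    peak_density: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_density == 0.0:
            self.peak_density = float(np.nanmax(self.grid))


def density_map(mosaic: ConeMosaic, grid_spec=None, k: int = 150,
                pixel_pitch_arcsec: float = 6.0) -> DensityMap:
    """Density = reciprocal of the mean bounded Voronoi-cell area of the
    ``k`` cones nearest each grid pixel.

    ``grid_spec`` is ``(x0, x1, y0, y1)`` in degrees; by default the grid
    covers the mosaic's bounding box shrunk by 2 x median ICD.  ``k`` is
    reduced (with a warning) if fewer bounded cells exist.
    """
    if not mosaic.tessellated:
        raise DegenerateInputError("mosaic must be tessellated first")
    good = mosaic.bounded
    n_good = int(good.sum())
    if n_good == 0:
        raise DegenerateInputError("no bounded Voronoi cells")
    if k > n_good:
        warnings.warn(f"k reduced from {k} to {n_good} bounded cells")
        k = n_good
    pts = mosaic.positions[good]
    areas = mosaic.cell_areas[good]

    pitch_deg = pixel_pitch_arcsec / DEG2ARCSEC
    if grid_spec is None:
        margin = 2.0 * np.nanmedian(mosaic.icd) / DEG2ARCSEC
        x0, y0 = mosaic.positions.min(axis=0) + margin
        x1, y1 = mosaic.positions.max(axis=0) - margin
    else:
        x0, x1, y0, y1 = grid_spec
    if x1 <= x0 or y1 <= y0:
        raise OutOfDomainError("empty density grid region")
    hull = Delaunay(mosaic.positions)
    corners = np.array([[x0, y0], [x0, y1], [x1, y0], [x1, y1]])
    if np.any(hull.find_simplex(corners) < 0):
        raise OutOfDomainError("density grid extends outside the mosaic hull")

    xs = np.arange(x0, x1 + pitch_deg / 2, pitch_deg)
    ys = np.arange(y0, y1 + pitch_deg / 2, pitch_deg)
    gx, gy = np.meshgrid(xs, ys)
    query = np.column_stack([gx.ravel(), gy.ravel()])
    tree = cKDTree(pts)
    _, idx = tree.query(query, k=k)
    if k == 1:
        idx = idx[:, None]
    dens = 1.0 / areas[idx].mean(axis=1)
    return DensityMap(dens.reshape(gy.shape), xs, ys, pixel_pitch_arcsec)


def find_cdc(dmap: DensityMap, top_fraction: float = 0.2) -> tuple[float, float]:
    """Cone density centroid: density-weighted centroid of the connected
    region at density >= (1 - top_fraction) x peak, component containing
    the peak pixel."""
    g = dmap.grid
    peak = np.nanmax(g)
    if not np.isfinite(peak) or peak == np.nanmin(g):
        raise DegenerateInputError("flat density map: CDC is ambiguous")
    mask = g >= (1.0 - top_fraction) * peak
    labels, _ = ndimage.label(mask)
    iy, ix = np.unravel_index(np.nanargmax(g), g.shape)
    comp = labels == labels[iy, ix]
    w = np.where(comp, g, 0.0)
    total = w.sum()
    cx = float((w.sum(axis=0) * dmap.x).sum() / total)
    cy = float((w.sum(axis=1) * dmap.y).sum() / total)
    dmap.cdc = (cx, cy)
    dmap.peak_density = float(peak)
    return cx, cy


def nyquist_limit(icd_arcsec) -> float | np.ndarray:
    """Nyquist sampling limit of a triangular mosaic: N_c = ICD * sqrt(3)/2
    (the row-to-row cone spacing), arcsec."""
    icd_arcsec = np.asarray(icd_arcsec, dtype=float)
    if np.any(icd_arcsec <= 0):
        raise DegenerateInputError("ICD must be positive")
    out = icd_arcsec * SQRT3 / 2.0
    return float(out) if out.ndim == 0 else out


def icd_from_density(density_cones_deg2) -> float | np.ndarray:
    """Invert the triangular-lattice area relation: a lattice of spacing s
    has one cone per (sqrt(3)/2) s^2, so s = sqrt(2 / (sqrt(3) d)).
    Returns arcsec."""
    d = np.asarray(density_cones_deg2, dtype=float)
    if np.any(d <= 0):
        raise DegenerateInputError("density must be positive")
    s_deg = np.sqrt(2.0 / (SQRT3 * d))
    out = s_deg * DEG2ARCSEC
    return float(out) if out.ndim == 0 else out


def density_from_icd(icd_arcsec) -> float | np.ndarray:
    """Triangular-lattice density, cones/deg^2, from spacing in arcsec."""
    s_deg = np.asarray(icd_arcsec, dtype=float) / DEG2ARCSEC
    out = 2.0 / (SQRT3 * s_deg**2)
    return float(out) if out.ndim == 0 else out


def triangular_lattice(spacing_deg: float, radius_deg: float,
                       center=(0.0, 0.0)) -> np.ndarray:
    """Perfect triangular lattice covering a disc. Rows are spaced
    spacing * sqrt(3)/2 apart with alternate rows offset by spacing/2."""
    s = spacing_deg
    row_h = s * SQRT3 / 2.0
    nrow = int(np.ceil(radius_deg / row_h)) + 1
    ncol = int(np.ceil(radius_deg / s)) + 1
    pts = []
    for j in range(-nrow, nrow + 1):
        off = (j % 2) * s / 2.0
        for i in range(-ncol, ncol + 1):
            pts.append((i * s + off, j * row_h))
    pts = np.array(pts)
    pts = pts[np.linalg.norm(pts, axis=1) <= radius_deg]
    return pts + np.asarray(center)


def hull_area(mosaic: ConeMosaic) -> float:
    """Convex-hull area of the cone centers, deg^2."""
    return float(ConvexHull(mosaic.positions).volume)
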