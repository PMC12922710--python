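"""The seeing-cones light-capture model and ISOA landing statistics."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from conedrift import capture as cap
from conedrift import mosaic as mz
from conedrift.errors import CurationError, DegenerateInputError
from conftest import LATTICE_SPACING_ARCSEC, gaussian_spot

S_DEG = LATTICE_SPACING_ARCSEC / 3600.0
FINE_PITCH = 1.0  # arcsec; fine enough that grid sums equal integrals


class TestApertures:
    def test_fwhm_arithmetic(self, lattice_mosaic):
        # ICD 35.69 -> FWHM 0.48*ICD, sigma = FWHM / 2.3548
        ap = cap.build_apertures(lattice_mosaic)
        i = int(np.argmin(np.linalg.norm(lattice_mosaic.positions, axis=1)))
        assert ap.fwhm_arcsec[i] == pytest.approx(0.48 * 35.69, rel=1e-9)
        assert ap.sigma_arcsec[i] == pytest.approx(0.48 * 35.69 / 2.3548, rel=1e-3)

    def test_uniform_lattice_apertures_identical(self, lattice_apertures,
                                                 lattice_mosaic):
        interior = np.linalg.norm(lattice_mosaic.positions, axis=1) < 0.1
        assert np.ptp(lattice_apertures.sigma_arcsec[interior]) < 1e-9

    def test_diameter_below_local_icd(self, jittered_mosaic):
        ap = cap.build_apertures(jittered_mosaic)
        ok = np.isfinite(jittered_mosaic.icd)
        assert np.all(ap.fwhm_arcsec[ok] < jittered_mosaic.icd[ok])
        assert np.all(ap.fwhm_arcsec[ok] > 0)

    def test_2sigma_convention(self, lattice_mosaic):
        ap = cap.build_apertures(lattice_mosaic, convention="2sigma")
        i = int(np.argmin(np.linalg.norm(lattice_mosaic.positions, axis=1)))
        assert ap.sigma_arcsec[i] == pytest.approx(0.48 * 35.69 / 2, rel=1e-9)

    def test_untessellated_raises(self):
        m = mz.ConeMosaic(mz.triangular_lattice(S_DEG, 0.05))
        with pytest.raises(DegenerateInputError):
            cap.build_apertures(m)

    def test_aperture_mass_mostly_inside_own_cell(self, lattice_mosaic):
        # numeric integration of the Gaussian over the hexagonal cell
        i = int(np.argmin(np.linalg.norm(lattice_mosaic.positions, axis=1)))
        sigma = cap.build_apertures(lattice_mosaic).sigma_arcsec[i]
        s = LATTICE_SPACING_ARCSEC
        # regular hexagon (Voronoi cell) with inradius s/2
        ang = np.deg2rad(np.arange(6) * 60 + 30)
        R = s / np.sqrt(3)
        hexagon = Polygon(np.column_stack([R * np.cos(ang), R * np.sin(ang)]))
        ax = np.arange(-s, s, 0.5)
        X, Y = np.meshgrid(ax, ax)
        g = np.exp(-(X**2 + Y**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2) * 0.25
        inside = np.array([hexagon.contains(Point(x, y))
                           for x, y in zip(X.ravel(), Y.ravel())])
        assert g.ravel()[inside].sum() > 0.9


def _center_cone(mosaic):
    return int(np.argmin(np.linalg.norm(mosaic.positions, axis=1)))


class TestCaptureTrial:
    def test_centered_spot_symmetric_across_neighbors(self, lattice_mosaic,
                                                      lattice_apertures):
        # small symmetric stimulus on a lattice cone: that cone captures the
        # most; its six neighbors capture equal fractions
        spot = gaussian_spot(8.0, FINE_PITCH, 80.0)
        amap = cap.capture_trial(spot, FINE_PITCH, lattice_apertures,
                                 np.zeros((1, 2)), support_sigmas=8.0)
        i = _center_cone(lattice_mosaic)
        assert amap.fraction[i] == amap.fraction.max()
        nb = lattice_mosaic.neighbors[i]
        assert len(nb) == 6
        assert np.ptp(amap.fraction[nb]) < 1e-6

    def test_lattice_translation_invariance(self, lattice_mosaic,
                                            lattice_apertures):
        spot = gaussian_spot(8.0, FINE_PITCH, 80.0)
        a0 = cap.capture_trial(spot, FINE_PITCH, lattice_apertures,
                               np.zeros((1, 2)))
        a1 = cap.capture_trial(spot, FINE_PITCH, lattice_apertures,
                               np.array([[S_DEG, 0.0]]))
        top0 = np.sort(a0.fraction)[-30:]
        top1 = np.sort(a1.fraction)[-30:]
        assert np.allclose(top0, top1, atol=1e-6)

    def test_fractions_normalized_and_seeing_rule(self, lattice_apertures):
        spot = gaussian_spot(8.0, FINE_PITCH, 80.0)
        amap = cap.capture_trial(spot, FINE_PITCH, lattice_apertures,
                                 np.zeros((1, 2)))
        assert amap.fraction.sum() == pytest.approx(1.0)
        assert np.array_equal(amap.seeing, amap.fraction > 0.01)

    def test_scale_invariance(self, lattice_apertures):
        spot = gaussian_spot(8.0, FINE_PITCH, 80.0)
        a1 = cap.capture_trial(spot, FINE_PITCH, lattice_apertures,
                               np.zeros((1, 2)))
        a2 = cap.capture_trial(2.0 * spot, FINE_PITCH, lattice_apertures,
                               np.zeros((1, 2)))
        assert np.allclose(a1.fraction, a2.fraction, atol=1e-12)
        assert np.array_equal(a1.seeing, a2.seeing)

    def test_zero_drift_independent_of_frame_count(self, lattice_apertures):
        spot = gaussian_spot(8.0, FINE_PITCH, 80.0)
        a1 = cap.capture_trial(spot, FINE_PITCH, lattice_apertures,
                               np.zeros((1, 2)))
        a5 = cap.capture_trial(spot, FINE_PITCH, lattice_apertures,
                               np.zeros((5, 2)))
        assert np.allclose(a1.fraction, a5.fraction, atol=1e-12)

    def test_two_frame_capture_matches_bruteforce(self, lattice_mosaic,
                                                  lattice_apertures):
        # oracle: direct per-cone double loop over pixels, frame by frame
        spot = gaussian_spot(10.0, 2.0, 60.0)
        shift = np.array([[0.0, 0.0], [S_DEG, 0.0]])
        amap = cap.capture_trial(spot, 2.0, lattice_apertures, shift,
                                 support_sigmas=8.0)
        pts = lattice_mosaic.positions * 3600.0
        near = np.linalg.norm(pts - np.array([S_DEG * 3600 / 2, 0.0]),
                              axis=1) < 60.0
        ax = np.arange(spot.shape[1]) * 2.0
        ax -= ax.mean()
        ay = ax[::-1]
        for i in np.flatnonzero(near):
            sig = lattice_apertures.sigma_arcsec[i]
            brute = 0.0
            for pos in shift:
                cx = pts[i, 0] - pos[0] * 3600.0
                cy = pts[i, 1] - pos[1] * 3600.0
                for r, y in enumerate(ay):
                    for c, x in enumerate(ax):
                        w = np.exp(-((x - cx)**2 + (y - cy)**2) / (2 * sig**2))
                        brute += spot[r, c] * w * 4.0 / (2 * np.pi * sig**2)
            assert amap.capture[i] == pytest.approx(brute, rel=1e-6, abs=1e-12)

    def test_two_frame_seeing_set_unions_frames(self, lattice_apertures):
        # with a 1-ICD slip the trial seeing set equals the union computed
        # frame-wise from the per-frame captures at the combined threshold
        spot = gaussian_spot(10.0, FINE_PITCH, 80.0)
        shift = np.array([[0.0, 0.0], [S_DEG, 0.0]])
        amap = cap.capture_trial(spot, FINE_PITCH, lattice_apertures, shift,
                                 keep_frames=True)
        per_frame = amap.per_frame
        union = set(np.flatnonzero(
            per_frame.sum(axis=0) / amap.total_capture > 0.01))
        assert set(amap.seeing_indices) == union

    def test_trace_gap_raises(self, lattice_apertures):
        spot = gaussian_spot(8.0, FINE_PITCH, 40.0)
        with pytest.raises(CurationError):
            cap.capture_trial(spot, FINE_PITCH, lattice_apertures,
                              np.zeros((2, 2)),
                              frame_valid=np.array([True, False]))


class TestHeatmapAndCore:
    def test_single_trial_counts(self):
        counts = cap.seeing_heatmap([[0, 3, 5]], 8)
        assert counts.tolist() == [1, 0, 0, 1, 0, 1, 0, 0]
        assert cap.core_fraction(counts, min_hits=10) == 0.0

    def test_identical_repeats_core_is_one(self):
        counts = cap.seeing_heatmap([[1, 2]] * 20, 5)
        assert cap.core_fraction(counts, min_hits=10) == 1.0

    def test_stable_fixation_high_core_matches_bruteforce(self):
        rng = np.random.default_rng(31)
        # 40 trials, a stable core of cones 0-9 plus occasional strays
        sets = []
        for _ in range(40):
            s = list(range(10))
            if rng.random() < 0.3:
                s.append(int(rng.integers(10, 50)))
            sets.append(s)
        counts = cap.seeing_heatmap(sets, 50)
        brute_core = sum(1 for c in counts if c > 10)
        brute_engaged = sum(1 for c in counts if c > 0)
        got = cap.core_fraction(counts, min_hits=10)
        assert got == pytest.approx(brute_core / brute_engaged)
        assert got > 0.4


class TestIsoa:
    def test_gaussian_cloud_contained_fraction_and_centroid(self):
        rng = np.random.default_rng(41)
        pts = rng.normal(0, 2.0, (1000, 2))
        out = cap.isoa(pts)
        assert 0.63 <= out.contained_fraction <= 0.73
        assert np.hypot(out.centroid[0] - pts[:, 0].mean(),
                        out.centroid[1] - pts[:, 1].mean()) < 0.1

    def test_translation_equivariance(self):
        rng = np.random.default_rng(41)
        pts = rng.normal(0, 2.0, (500, 2))
        a = cap.isoa(pts)
        b = cap.isoa(pts + np.array([2.0, 0.0]))
        assert b.centroid[0] - a.centroid[0] == pytest.approx(2.0, abs=1e-6)
        assert b.centroid[1] - a.centroid[1] == pytest.approx(0.0, abs=1e-6)
        assert b.area == pytest.approx(a.area, rel=1e-6)

    def test_ring_contained_fraction_matches_point_in_region_test(self):
        rng = np.random.default_rng(43)
        ang = rng.uniform(0, 2 * np.pi, 400)
        r = 5.0 + rng.normal(0, 0.3, 400)
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        out = cap.isoa(pts)
        # oracle: brute-force membership of each point in the superlevel set
        from scipy.stats import gaussian_kde
        kde = gaussian_kde(pts.T, bw_method="silverman")
        member = kde(pts.T) >= out.level
        assert out.contained_fraction == pytest.approx(member.mean(), abs=1e-9)
        assert 0.6 <= out.contained_fraction <= 0.76

    def test_cdc_offset(self):
        rng = np.random.default_rng(44)
        pts = rng.normal([3.0, 0.0], 1.0, (300, 2))
        out = cap.isoa(pts, cdc=(0.0, 0.0))
        assert out.offset_to_cdc == pytest.approx(3.0, abs=0.3)

    def test_degenerate_points_zero_area(self):
        pts = np.tile([1.0, 2.0], (25, 1))
        with pytest.warns(UserWarning):
            out = cap.isoa(pts)
        assert out.area == 0.0

    def test_too_few_points_raises(self):
        with pytest.raises(DegenerateInputError):
            cap.isoa(np.zeros((5, 2)))
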