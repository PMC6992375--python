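"""Radial profiling, peak detection, spacing estimation and lens
reconstruction."""

import numpy as np
import pytest

from irmkit.frames import IRMFrame
from irmkit.fringes import (
    FringeSet,
    detect_fringe_peaks,
    percent_deviation,
    radial_profile,
    reconstruct_lens,
    spacing_from_peaks,
)
from irmkit.optics import fringe_spacing
from irmkit.simulate import (
    LENS_NA,
    LENS_PIXEL_SIZE,
    LensGeometry,
    lens_height_map,
    lens_optical_config,
    render_irm,
)


def _synthetic_radial_frame(f, n=201, pixel_size=1.0):
    """Image whose intensity is a pure function of radius from the centre."""
    c = n // 2
    ii, jj = np.mgrid[0:n, 0:n]
    r = np.hypot(ii - c, jj - c)
    return IRMFrame(f(r)[None], (488.0,), pixel_size), (float(c), float(c))


class TestRadialProfile:
    def test_radially_symmetric_image_reproduces_its_generator(self):
        f = lambda r: 1.0 + np.cos(2 * np.pi * r / 40.0)
        frame, center = _synthetic_radial_frame(f)
        prof = radial_profile(frame, center)
        expected = f(prof.radii / frame.pixel_size)
        # annulus means deviate from point samples by the binning error
        inner = (prof.radii > 5) & (prof.radii < 80)
        assert np.allclose(prof.intensities[488.0][inner], expected[inner], atol=0.08)

    def test_uniform_image_gives_a_flat_profile(self):
        frame, center = _synthetic_radial_frame(lambda r: np.full_like(r, 3.0))
        prof = radial_profile(frame, center)
        assert np.allclose(prof.intensities[488.0], 3.0)

    def test_center_outside_image_rejected(self):
        frame, _ = _synthetic_radial_frame(lambda r: r)
        with pytest.raises(ValueError):
            radial_profile(frame, (-5.0, 10.0))

    def test_first_lens_maximum_sits_at_the_122_nm_radius(self, lens_frame, lens_geom):
        """The innermost bright ring is where z(x) crosses the N = 0
        constructive height λ/4n = 122 nm."""
        prof = radial_profile(lens_frame)
        fs = detect_fringe_peaks(prof, 0.1, gap_index=1.0)
        first = fs.peaks[488.0][0]
        r_um = first.radius
        # invert z(x): x = sqrt(2 R z - z^2), z = 122 nm, R = 20 mm = 2e4 μm
        r_expected = np.sqrt(2 * 20.0e3 * 0.122 - 0.122 ** 2)  # μm
        assert r_um == pytest.approx(r_expected, abs=2 * lens_frame.pixel_size)
        assert first.height == pytest.approx(122.0, abs=0.1)


class TestPeakDetection:
    def test_pure_cosine_peaks_are_equally_spaced(self):
        radii = np.arange(300) * 1.0
        trace = 1.0 + np.cos(2 * np.pi * radii / 40.0)
        prof_frame, center = _synthetic_radial_frame(
            lambda r: 1.0 + np.cos(2 * np.pi * r / 40.0), n=601)
        prof = radial_profile(prof_frame, center)
        fs = detect_fringe_peaks(prof, 0.1)
        r = np.array([p.radius for p in fs.peaks[488.0]])
        assert len(r) >= 5
        assert np.allclose(np.diff(r), 40.0, atol=1.0)
        assert [p.order for p in fs.peaks[488.0]] == list(range(len(r)))

    def test_fringe_free_profile_yields_no_peaks(self):
        """A drifting, lightly noisy profile with no fringe structure:
        the brute-force oracle confirms no excursion reaches a 0.2-of-range
        prominence, so detection must return an empty set with a warning."""
        rng = np.random.default_rng(0)
        from irmkit.fringes import RadialProfile
        radii = np.arange(100) + 0.5
        trace = np.linspace(1.0, 2.0, 100) + 0.01 * rng.standard_normal(100)
        prof = RadialProfile(radii, {488.0: trace}, (0.0, 0.0), 1.0)
        from scipy.signal import find_peaks
        oracle_idx, _ = find_peaks(trace, prominence=0.2 * np.ptp(trace))
        assert len(oracle_idx) == 0
        with pytest.warns(UserWarning, match="no fringe peaks"):
            fs = detect_fringe_peaks(prof, min_prominence=0.2)
        assert fs.peaks[488.0] == []


class TestSpacing:
    def test_two_peak_heights_give_their_difference_exactly(self):
        # radii chosen so that z(x) = 244 and 488 nm for R = 20 mm
        geom = LensGeometry(20.0)
        r1 = np.sqrt(2 * 20e3 * 0.244 - 0.244 ** 2)
        r2 = np.sqrt(2 * 20e3 * 0.488 - 0.488 ** 2)
        from irmkit.fringes import FringePeak
        fs = FringeSet({488.0: [FringePeak(r1, 0, 122.0), FringePeak(r2, 1, 366.0)]})
        fs = spacing_from_peaks(fs, geom)
        mean, sd = fs.spacing[488.0]
        assert mean == pytest.approx(244.0, abs=1e-6)
        assert sd == 0.0

    def test_single_peak_is_insufficient(self):
        from irmkit.fringes import FringePeak
        fs = FringeSet({488.0: [FringePeak(100.0, 0, 122.0)]})
        with pytest.raises(ValueError, match="peak"):
            spacing_from_peaks(fs, LensGeometry(20.0))

    def test_rendered_543_lens_recovers_the_271_5_nm_spacing(self):
        """Forward-model ground truth: λ = 543 nm in air spaces fringes by
        271.5 nm; the full analysis recovers it within 2 nm."""
        geom = LensGeometry(20.0)
        cfg = lens_optical_config((543.0,))
        hm = lens_height_map(geom, 700 * LENS_PIXEL_SIZE, LENS_PIXEL_SIZE)
        frame = render_irm(hm, cfg, na=LENS_NA)
        prof = radial_profile(frame)
        fs = spacing_from_peaks(detect_fringe_peaks(prof, 0.1, 1.0), geom)
        mean, sd = fs.spacing[543.0]
        assert mean == pytest.approx(271.5, abs=2.0)

    def test_percent_deviation_formula(self):
        assert percent_deviation(249.0, 244.0) == pytest.approx(100 * 5 / 244)
        with pytest.raises(ValueError):
            percent_deviation(249.0, 0.0)


class TestMultiwavelengthStructure:
    def test_channel_peaks_interleave_by_wavelength(self):
        """Spectral separation: the N-th 543-nm ring sits outside the N-th
        488-nm ring at every order."""
        geom = LensGeometry(20.0)
        cfg = lens_optical_config((488.0, 543.0))
        hm = lens_height_map(geom, 700 * LENS_PIXEL_SIZE, LENS_PIXEL_SIZE)
        frame = render_irm(hm, cfg, na=LENS_NA)
        fs = detect_fringe_peaks(radial_profile(frame), 0.1, 1.0)
        r488 = [p.radius for p in fs.peaks[488.0]]
        r543 = [p.radius for p in fs.peaks[543.0]]
        for a, b in zip(r488, r543):
            assert b > a

    def test_peak_count_grows_with_aperture(self):
        geom = LensGeometry(20.0)
        cfg = lens_optical_config((488.0,))
        counts = []
        for n_px in (300, 500, 700):
            hm = lens_height_map(geom, n_px * LENS_PIXEL_SIZE, LENS_PIXEL_SIZE)
            frame = render_irm(hm, cfg, na=LENS_NA)
            fs = detect_fringe_peaks(radial_profile(frame), 0.1, 1.0)
            counts.append(len(fs.peaks[488.0]))
        assert counts[0] < counts[1] < counts[2]

    def test_noise_free_spacing_within_one_percent_of_theory(self):
        """Recovered spacing equals λ/(2 n_gap) within 1% for each laser
        line used on the calibration lens."""
        geom = LensGeometry(20.0)
        for lam in (488.0, 514.0, 543.0):
            cfg = lens_optical_config((lam,))
            hm = lens_height_map(geom, 700 * LENS_PIXEL_SIZE, LENS_PIXEL_SIZE)
            frame = render_irm(hm, cfg, na=LENS_NA)
            fs = spacing_from_peaks(detect_fringe_peaks(radial_profile(frame), 0.1, 1.0), geom)
            mean, _ = fs.spacing[lam]
            assert percent_deviation(mean, fringe_spacing(lam, 1.0)) < 1.0


class TestReconstruction:
    def test_center_pixel_maps_to_zero_height(self, lens_frame, lens_geom):
        cloud = reconstruct_lens(lens_frame, lens_geom)
        nearest = cloud.loc[(cloud.x_um ** 2 + cloud.y_um ** 2).idxmin()]
        assert nearest.z_nm == pytest.approx(0.0, abs=1.0)

    def test_assigned_heights_match_ground_truth_geometry(self, lens_geom, lens_cfg):
        """Reconstruction of a rendered lens: RMSE between assigned z and the
        generator's ground truth is < 1 nm (same geometry both sides)."""
        hm = lens_height_map(lens_geom, 300 * LENS_PIXEL_SIZE, LENS_PIXEL_SIZE)
        frame = render_irm(hm, lens_cfg, na=LENS_NA)
        n = hm.heights.shape[0]
        center = (n / 2, n / 2)  # the generator's contact pixel
        cloud = reconstruct_lens(frame, lens_geom, center=center)
        truth = hm.heights.ravel()
        assert len(cloud) == truth.size
        rmse = np.sqrt(np.mean((cloud.z_nm.to_numpy() - truth) ** 2))
        assert rmse < 1.0

    def test_pixels_beyond_aperture_are_excluded(self, lens_cfg):
        geom = LensGeometry(20.0, aperture=0.4)  # 400 μm aperture
        hm = lens_height_map(geom, 300.0, 1.0)
        frame = render_irm(hm, lens_cfg)
        # analysis window larger than the aperture: corners must be dropped
        big = IRMFrame(np.pad(frame.data, ((0, 0), (0, 200), (0, 200)), mode="edge"),
                       frame.wavelengths, frame.pixel_size)
        cloud = reconstruct_lens(big, geom, center=(150.0, 150.0))
        assert len(cloud) < big.shape[0] * big.shape[1]
        r = np.hypot(cloud.x_um, cloud.y_um)
        assert r.max() <= 200.0 + 1e-6
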