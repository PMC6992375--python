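"""Line profiling, color-ordering classification and basal-profile
reconstruction."""

import numpy as np
import pytest

from irmkit.frames import IRMFrame
from irmkit.simulate import CellScene, CellSpec, gliding_movie
from irmkit.topography import (
    Anchor,
    InconsistentAnchorsError,
    TopographySegment,
    adhesion_timeseries,
    autocorrelation,
    classify_color_ordering,
    line_profile,
    reconstruct_basal_profile,
)

from conftest import render_cell


class TestLineProfile:
    def test_width_one_equals_direct_sampling(self, cell_cfg):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (2, 40, 40))
        frame = IRMFrame(img, (488.0, 635.0), 0.1)
        line = np.array([[0.5, 2.0], [3.5, 2.0]])  # along a pixel row
        prof = line_profile(frame, line, width=1)
        row = 20  # y = 2.0 μm / 0.1
        cols = np.round(prof.arclength / 0.1 + 5).astype(int)
        assert np.allclose(prof.intensities[488.0], img[0, row, cols], atol=1e-9)

    def test_uniform_background_gives_flat_traces(self, cell_cfg):
        frame = IRMFrame(np.full((2, 30, 30), 0.7), (488.0, 635.0), 0.1)
        prof = line_profile(frame, np.array([[0.5, 1.5], [2.5, 1.5]]), 3)
        for lam in (488.0, 635.0):
            assert np.allclose(prof.intensities[lam], 0.7)

    def test_short_wavelength_maximum_precedes_long_on_an_incline(self, lift_frame):
        """Along a rising basal surface the 488-nm fringe comes strictly
        before the 635-nm fringe."""
        prof = line_profile(lift_frame, np.array([[2.0, 5.0], [7.0, 5.0]]), 3)
        s488 = prof.arclength[np.argmax(prof.intensities[488.0])]
        s635 = prof.arclength[np.argmax(prof.intensities[635.0])]
        assert s488 < s635

    def test_polyline_leaving_the_image_is_truncated_with_warning(self, lift_frame):
        with pytest.warns(UserWarning, match="exits the image"):
            prof = line_profile(lift_frame, np.array([[5.0, 5.0], [20.0, 5.0]]), 3)
        assert prof.arclength[-1] < 15.0

    def test_even_width_rejected(self, lift_frame):
        with pytest.raises(ValueError):
            line_profile(lift_frame, np.array([[2.0, 5.0], [7.0, 5.0]]), width=2)


class TestColorOrdering:
    def test_single_lift_cell_classified_adhered_then_incline(self, lift_frame, cell_cfg):
        """Leading pole attached, body rising to 180 nm: an adhered stretch
        followed by an incline anchored at 91.7 nm (488) then 119.3 nm (635)."""
        segs = classify_color_ordering(
            line_profile(lift_frame, np.array([[2.0, 5.0], [7.0, 5.0]]), 3), cell_cfg)
        directions = [s.direction for s in segs]
        assert directions == ["adhered", "incline"]
        incline = segs[1]
        heights = [round(a.height, 1) for a in sorted(incline.anchors,
                                                      key=lambda a: a.arclength)]
        assert heights == [91.7, 119.4]
        assert [a.order for a in incline.anchors] == [0, 0]
        assert not incline.ambiguous

    def test_undulating_cell_shows_incline_decline_incline(self, undulating_frame, cell_cfg):
        segs = classify_color_ordering(
            line_profile(undulating_frame, np.array([[2.0, 5.0], [7.0, 5.0]]), 3), cell_cfg)
        slopes = [s.direction for s in segs if s.direction in ("incline", "decline")]
        assert slopes == ["incline", "decline", "incline"]

    def test_fully_adhered_cell_is_one_adhered_segment(self, straight_line, cell_cfg):
        frame = render_cell(CellSpec(straight_line, profile="adhered"), cell_cfg)
        prof = line_profile(frame, straight_line, 3)
        segs = classify_color_ordering(prof, cell_cfg)
        assert [s.direction for s in segs] == ["adhered"]
        assert segs[0].anchors == []
        # the adhered stretch spans (essentially) the whole body
        assert segs[0].end - segs[0].start > 0.8 * (prof.arclength[-1] - prof.arclength[0])

    def test_declining_cell_reverses_the_color_order(self, straight_line, cell_cfg):
        cell = CellSpec(straight_line[::-1].copy(), profile="single_lift",
                        params={"lift_nm": 180.0})
        frame = render_cell(cell, cell_cfg)
        segs = classify_color_ordering(line_profile(frame, straight_line, 3), cell_cfg)
        assert "decline" in [s.direction for s in segs]
        assert "incline" not in [s.direction for s in segs]

    def test_more_than_two_channels_unsupported(self, cell_cfg):
        frame = IRMFrame(np.random.default_rng(0).uniform(0.1, 1, (3, 30, 30)),
                         (488.0, 543.0, 635.0), 0.1)
        prof = line_profile(frame, np.array([[0.5, 1.5], [2.5, 1.5]]), 3)
        with pytest.raises(ValueError, match="two wavelengths"):
            classify_color_ordering(prof, cell_cfg)


class TestBasalReconstruction:
    def test_interpolation_stays_between_anchor_heights(self):
        seg = TopographySegment(2.0, 2.6, "incline", anchors=[
            Anchor(2.0, 488.0, 0, 91.7), Anchor(2.6, 635.0, 0, 119.3)])
        bp = reconstruct_basal_profile([seg])
        mid = np.interp(2.3, bp.arclength, bp.height)
        assert 91.7 < mid < 119.3

    def test_single_lift_reconstruction_bounded_by_fringe_ladder(self, lift_frame, cell_cfg):
        """Ground truth 180 nm: the reconstructed maximum must land between
        the last observed anchor (119.3 nm) and the next unobserved order
        (the 488-nm N = 1 destructive height, 183.5 nm)."""
        segs = classify_color_ordering(
            line_profile(lift_frame, np.array([[2.0, 5.0], [7.0, 5.0]]), 3), cell_cfg)
        bp = reconstruct_basal_profile(segs)
        assert 119.3 <= bp.max_height <= 183.5

    def test_contradictory_anchor_order_raises(self):
        seg = TopographySegment(1.0, 2.0, "decline", anchors=[
            Anchor(1.0, 488.0, 0, 91.7), Anchor(2.0, 635.0, 0, 119.3)])
        with pytest.raises(InconsistentAnchorsError, match=r"\[1.00, 2.00\]"):
            reconstruct_basal_profile([seg])

    def test_anchorless_segments_reconstruct_flat_zero_with_warning(self):
        seg = TopographySegment(0.0, 5.0, "adhered")
        with pytest.warns(UserWarning, match="flat"):
            bp = reconstruct_basal_profile([seg])
        assert np.allclose(bp.height, 0.0)
        assert bp.max_height == 0.0


class TestAdhesionTimeseries:
    def test_static_adhered_cell_stays_fully_adhered(self, straight_line, cell_cfg):
        cell = CellSpec(straight_line, profile="adhered", cell_id=0)
        scene = CellScene([cell], fluctuation_step=0.0)
        movie = gliding_movie(scene, 4, cell_cfg, seed=0, shape=(100, 100))
        polylines = [movie.polylines[f][0] for f in range(4)]
        df, acf = adhesion_timeseries(movie.frames, polylines, cell_cfg)
        assert len(df) == 4
        assert np.all(df["adhered_fraction"] > 0.8)
        assert np.all(df["max_height_nm"] == 0.0)

    def test_sinusoidal_lift_series_is_periodic_by_autocorrelation(self):
        """Closed-form oracle: the biased autocorrelation estimator of a
        sampled sinusoid is (1 - lag/n)·cos(ω·lag), which exceeds 0.5 at the
        true period — a strictly periodic lift is flagged as periodic."""
        period, n = 10, 60
        t = np.arange(n)
        series = 135.0 + 45.0 * np.sin(2 * np.pi * t / period)
        acf = autocorrelation(series)
        assert acf[period] > 0.5
        assert acf[period] == pytest.approx((1 - period / n) * np.cos(2 * np.pi), abs=0.05)

    def test_reflected_random_walk_is_aperiodic(self):
        """Ground-truth oracle on the simulator's fluctuation process: the
        lift series decorrelates, with no autocorrelation peak > 0.5 beyond
        its decorrelation lag."""
        from irmkit.simulate import _reflect
        rng = np.random.default_rng(4)
        lift, series = 100.0, []
        for _ in range(300):
            series.append(lift)
            lift = _reflect(lift + rng.normal(0, 60.0), 0.0, 200.0)
        acf = autocorrelation(np.array(series))
        assert np.all(np.abs(acf[5:]) < 0.5)

    def test_missing_polyline_skips_the_frame(self, straight_line, cell_cfg):
        cell = CellSpec(straight_line, profile="adhered", cell_id=0)
        movie = gliding_movie(CellScene([cell]), 3, cell_cfg, seed=0, shape=(100, 100))
        polylines = {0: movie.polylines[0][0], 2: movie.polylines[2][0]}
        with pytest.warns(UserWarning, match="frame 1"):
            df, _ = adhesion_timeseries(movie.frames, polylines, cell_cfg)
        assert list(df["frame"]) == [0, 2]
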