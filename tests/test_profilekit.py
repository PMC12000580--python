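"""Unit and property tests for the line-profile measurement engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uexmtools import profilekit as pk
from uexmtools import synthgen as sg

from conftest import make_profile


# ---------------------------------------------------------------------------
# detect_extent
# ---------------------------------------------------------------------------


class TestDetectExtent:
    def test_hand_computed_half_max_crossings(self):
        # threshold 5 crosses between (3,4)->(4,10) and (6,10)->(7,4)
        prof = make_profile([0, 0, 1, 4, 10, 10, 10, 4, 1, 0])
        ext = pk.detect_extent(prof, "ch")
        assert ext.start_nm == pytest.approx(3 + 1 / 6, abs=1e-12)
        assert ext.end_nm == pytest.approx(6 + 5 / 6, abs=1e-12)
        assert ext.length_nm == pytest.approx(11 / 3, abs=1e-12)
        assert ext.threshold_value == pytest.approx(5.0)

    def test_flat_profile_reports_no_signal(self):
        assert pk.detect_extent(make_profile(np.zeros(20)), "ch") is None
        assert pk.detect_extent(make_profile(np.full(20, 7.0)), "ch") is None

    def test_mirror_reversal_swaps_start_end(self):
        vals = np.array([0, 0, 1, 4, 10, 10, 10, 4, 1, 0, 0, 0], dtype=float)
        fwd = pk.detect_extent(make_profile(vals), "ch")
        rev = pk.detect_extent(make_profile(vals[::-1]), "ch")
        total = 11.0  # last position
        assert rev.length_nm == pytest.approx(fwd.length_nm, abs=1e-12)
        assert rev.start_nm == pytest.approx(total - fwd.end_nm, abs=1e-12)
        assert rev.end_nm == pytest.approx(total - fwd.start_nm, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e4),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_scale_invariance(self, scale, seed):
        """Half-max extents are invariant under positive intensity scaling."""
        rng = np.random.default_rng(seed)
        a, b = sorted(rng.uniform(10, 90, size=2))
        if b - a < 2:
            b = a + 2
        x = np.arange(100.0)
        vals = np.clip(np.minimum(x - a, b - x), 0, 5)
        base = pk.detect_extent(make_profile(vals), "ch")
        scaled = pk.detect_extent(make_profile(vals * scale), "ch")
        assert scaled.start_nm == pytest.approx(base.start_nm, rel=1e-9, abs=1e-9)
        assert scaled.end_nm == pytest.approx(base.end_nm, rel=1e-9, abs=1e-9)

    def test_nonzero_baseline_offset_is_removed(self):
        # camera offset of 100 must not move the crossings
        vals = np.array([0, 0, 1, 4, 10, 10, 10, 4, 1, 0], dtype=float)
        ext0 = pk.detect_extent(make_profile(vals), "ch")
        ext1 = pk.detect_extent(make_profile(vals + 100.0), "ch")
        assert ext1.start_nm == pytest.approx(ext0.start_nm, abs=1e-9)
        assert ext1.end_nm == pytest.approx(ext0.end_nm, abs=1e-9)


# ---------------------------------------------------------------------------
# resample_profile
# ---------------------------------------------------------------------------


class TestResample:
    def test_identity_at_subdivision_one(self):
        prof = make_profile([0, 6, 3, 9])
        out = pk.resample_profile(prof, 1)
        np.testing.assert_array_equal(out.positions_nm, prof.positions_nm)
        np.testing.assert_array_equal(out.intensities["ch"], prof.intensities["ch"])

    def test_hand_linear_interpolation(self):
        prof = make_profile([0.0, 6.0], step_nm=10.0)
        out = pk.resample_profile(prof, 3)
        np.testing.assert_allclose(out.intensities["ch"], [0, 2, 4, 6])
        np.testing.assert_allclose(out.positions_nm, [0, 10 / 3, 20 / 3, 10])
        assert out.sampling_step_nm == pytest.approx(10 / 3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(min_value=0, max_value=2**31 - 1),
        sub=st.integers(min_value=1, max_value=7),
    )
    def test_trapezoid_integral_preserved(self, seed, sub):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 10, size=rng.integers(5, 40))
        prof = make_profile(vals, step_nm=2.5)
        out = pk.resample_profile(prof, sub)
        i0 = np.trapezoid(prof.intensities["ch"], prof.positions_nm)
        i1 = np.trapezoid(out.intensities["ch"], out.positions_nm)
        assert i1 == pytest.approx(i0, abs=1e-9)


# ---------------------------------------------------------------------------
# extract_line_profile
# ---------------------------------------------------------------------------


class TestExtractLineProfile:
    def test_constant_image_gives_constant_profile(self):
        img = pk.ImagePlane({"a": np.full((20, 20), 7.0)}, pixel_size_nm=10)
        prof = pk.extract_line_profile(img, (2, 10), (17, 10), width_px=3)
        np.testing.assert_allclose(prof.intensities["a"], 7.0)
        assert prof.sampling_step_nm == pytest.approx(10.0)

    def test_coincident_endpoints_rejected(self):
        img = pk.ImagePlane({"a": np.zeros((10, 10))}, pixel_size_nm=10)
        with pytest.raises(ValueError, match="coincide"):
            pk.extract_line_profile(img, (3, 3), (3, 3))

    def test_wide_line_exiting_image_rejected(self):
        img = pk.ImagePlane({"a": np.zeros((10, 10))}, pixel_size_nm=10)
        with pytest.raises(ValueError, match="exits"):
            pk.extract_line_profile(img, (5, 0), (5, 9), width_px=21)

    def test_cross_section_of_side_view_hits_both_walls(self, noiseless_model):
        """A vertical scan across a noiseless side view shows two plateaus
        separated by the tubulin diameter, matching direct pixel indexing."""
        truth = sg.CentrioleTruth(view="side", marker_model="absent", marker_length_nm=0)
        img, _ = sg.generate_centriole_image(truth, noiseless_model, canvas_px=(64, 64))
        cx = (64 - 1) / 2
        prof = pk.extract_line_profile(img, (cx, 4), (cx, 59), width_px=1)
        ext = pk.detect_extent(pk.resample_profile(prof, 3), "tubulin")
        outer = truth.tubulin_diameter_nm + truth.wall_thickness_nm
        assert ext.length_nm == pytest.approx(outer, abs=noiseless_model.pixel_size_nm)
        # oracle: direct indexing of the rendered column
        col = img.channels["tubulin"][:, int(cx)]
        lit = np.nonzero(col > col.max() / 2)[0]
        gap_centers = (lit.max() - lit.min()) * noiseless_model.pixel_size_nm
        assert gap_centers == pytest.approx(
            truth.tubulin_diameter_nm + truth.wall_thickness_nm - noiseless_model.pixel_size_nm,
            abs=2 * noiseless_model.pixel_size_nm,
        )

    def test_width_averaging_is_identity_on_uniform_structure(self):
        arr = np.tile(np.linspace(0, 9, 10), (11, 1))  # uniform across rows
        img = pk.ImagePlane({"a": arr}, pixel_size_nm=10)
        p1 = pk.extract_line_profile(img, (0, 5), (9, 5), width_px=1)
        p5 = pk.extract_line_profile(img, (0, 5), (9, 5), width_px=5)
        np.testing.assert_allclose(p5.intensities["a"], p1.intensities["a"], atol=1e-9)


# ---------------------------------------------------------------------------
# expansion calibration / correction
# ---------------------------------------------------------------------------


class TestExpansion:
    @pytest.mark.parametrize(
        "disk,expected", [(16.0, 4.0), (4.0, 1.0), (17.2, 4.3)]
    )
    def test_factor_is_disk_over_punch(self, disk, expected):
        assert pk.calibrate_expansion(disk).factor == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            pk.calibrate_expansion(0.0)
        with pytest.raises(ValueError):
            pk.calibrate_expansion(16.0, punch_diameter_mm=-1)

    def test_correction_divides_all_lengths(self, cal4):
        ext = pk.SignalExtent("tubulin", 100.0, 580.0, 10.0, 5.0)
        m = pk.CentrioleMeasurement(
            id="c1", view="side", extents={"tubulin": ext},
            length_nm={"tubulin": 480.0},
        )
        c = pk.correct_measurement(m, cal4)
        assert c.length_nm["tubulin"] == pytest.approx(120.0)
        assert c.extents["tubulin"].start_nm == pytest.approx(25.0)
        assert c.space == "corrected"
        assert c.expansion_factor == pytest.approx(4.0)

    def test_factor_one_changes_only_the_flag(self):
        cal = pk.calibrate_expansion(4.0)
        m = pk.CentrioleMeasurement(
            id="c1", view="side",
            extents={"tubulin": pk.SignalExtent("tubulin", 0.0, 390.0, 1.0, 0.5)},
            length_nm={"tubulin": 390.0},
        )
        c = pk.correct_measurement(m, cal)
        assert c.length_nm["tubulin"] == pytest.approx(390.0)
        assert c.space == "corrected"

    def test_double_correction_rejected(self, cal4):
        m = pk.CentrioleMeasurement(
            id="c1", view="side",
            extents={"tubulin": pk.SignalExtent("tubulin", 0.0, 390.0, 1.0, 0.5)},
            length_nm={"tubulin": 390.0},
        )
        c = pk.correct_measurement(m, cal4)
        with pytest.raises(ValueError, match="already"):
            pk.correct_measurement(c, cal4)

    def test_corrected_diameter_lands_in_em_reference_band(self, cal4):
        """Isotropy control: a 4x-expanded synthetic centriole with true
        biological diameter 200 nm measures back inside 200 +/- 12 nm."""
        truth = sg.CentrioleTruth(view="bottom", tubulin_diameter_nm=200.0)
        diams = []
        for i in range(20):
            prof, _ = sg.generate_profile(truth, sg.ImagingModel(rng_seed=i), "radial")
            m = pk.measure_bottom_view(prof, cal4, mode="peak_to_peak")
            diams.append(m.diameter_nm["tubulin"])
        lo, hi = 200 - 12, 200 + 12
        assert lo <= np.mean(diams) <= hi

    def test_correct_then_measure_equals_measure_then_correct(self, cal4):
        """Measuring in gel space then dividing by the factor agrees with
        measuring an already-rescaled profile."""
        truth = sg.CentrioleTruth(view="side", marker_model="absent", marker_length_nm=0)
        model = sg.ImagingModel(
            pixel_size_nm=10, psf_sigma_nm=30, background_offset=0,
            read_noise_sd=0, shot_noise=False, expansion_factor=4,
        )
        prof, _ = sg.generate_profile(truth, model, "longitudinal")
        m_gel = pk.measure_side_view(prof, cal=None)
        corrected = pk.correct_measurement(m_gel, cal4)
        shrunk = pk.LineProfile(
            prof.positions_nm / 4, {k: v.copy() for k, v in prof.intensities.items()},
            prof.sampling_step_nm / 4, space="corrected",
        )
        m_direct = pk.measure_side_view(shrunk, cal=None)
        assert corrected.length_nm["tubulin"] == pytest.approx(
            m_direct.length_nm["tubulin"], rel=1e-9
        )


# ---------------------------------------------------------------------------
# side / bottom measurement
# ---------------------------------------------------------------------------


class TestMeasureViews:
    def test_side_view_length_recovers_geometry(self, noiseless_model):
        truth = sg.CentrioleTruth(view="side", marker_model="absent", marker_length_nm=0)
        prof, _ = sg.generate_profile(truth, noiseless_model, "longitudinal")
        m = pk.measure_side_view(prof)
        step = noiseless_model.pixel_size_nm / 3
        assert m.length_nm["tubulin"] == pytest.approx(390.0, abs=step)

    def test_flat_marker_recorded_absent(self, noiseless_model):
        truth = sg.CentrioleTruth(view="side", marker_model="absent", marker_length_nm=0)
        prof, _ = sg.generate_profile(truth, noiseless_model, "longitudinal")
        m = pk.measure_side_view(prof)
        assert m.extents["marker"] is None
        assert "marker" not in m.length_nm
        assert m.extents["tubulin"] is not None

    def test_intensity_doubling_leaves_extents_unchanged(self, noiseless_model):
        truth = sg.CentrioleTruth(view="side")
        prof, _ = sg.generate_profile(truth, noiseless_model, "longitudinal")
        doubled = pk.LineProfile(
            prof.positions_nm.copy(),
            {k: 2 * v for k, v in prof.intensities.items()},
            prof.sampling_step_nm,
        )
        m1 = pk.measure_side_view(prof)
        m2 = pk.measure_side_view(doubled)
        for ch in m1.length_nm:
            assert m2.length_nm[ch] == pytest.approx(m1.length_nm[ch], rel=1e-9)

    def test_no_tubulin_signal_is_an_error(self):
        prof = make_profile(np.zeros(30), channel="tubulin")
        with pytest.raises(ValueError, match="tubulin"):
            pk.measure_side_view(prof)

    def test_bottom_view_peak_to_peak_recovers_diameter(self, noiseless_model):
        truth = sg.CentrioleTruth(view="bottom", marker_model="absent", marker_length_nm=0)
        prof, _ = sg.generate_profile(truth, noiseless_model, "radial")
        m = pk.measure_bottom_view(prof, mode="peak_to_peak")
        step = noiseless_model.pixel_size_nm / 3
        assert m.diameter_nm["tubulin"] == pytest.approx(240.0, abs=step)
        assert m.diameter_mode == "peak_to_peak"

    def test_outer_half_max_brackets_peak_to_peak(self):
        truth = sg.CentrioleTruth(view="bottom", marker_model="absent", marker_length_nm=0)
        for seed in range(5):
            model = sg.ImagingModel(rng_seed=seed)
            prof, _ = sg.generate_profile(truth, model, "radial")
            p2p = pk.measure_bottom_view(prof, mode="peak_to_peak")
            ohm = pk.measure_bottom_view(prof, mode="outer_half_max")
            assert ohm.diameter_nm["tubulin"] >= p2p.diameter_nm["tubulin"]

    def test_single_peak_profile_is_an_error(self):
        x = np.arange(60.0)
        vals = np.exp(-0.5 * ((x - 30) / 4) ** 2)
        prof = make_profile(vals, channel="tubulin")
        with pytest.raises(ValueError, match="two peaks"):
            pk.measure_bottom_view(prof)

    def test_marker_ring_diameter_measured_alongside_tubulin(self, noiseless_model):
        truth = sg.CentrioleTruth(view="bottom", marker_model="proximal_ring",
                                  marker_diameter_nm=240.0)
        prof, _ = sg.generate_profile(truth, noiseless_model, "radial")
        m = pk.measure_bottom_view(prof, mode="peak_to_peak")
        assert m.diameter_nm["marker"] == pytest.approx(240.0, abs=noiseless_model.pixel_size_nm)


# ---------------------------------------------------------------------------
# relative positioning
# ---------------------------------------------------------------------------


def _side_measurement(tub, marker=None):
    extents = {"tubulin": pk.SignalExtent("tubulin", tub[0], tub[1], 10.0, 5.0)}
    extents["marker"] = (
        pk.SignalExtent("marker", marker[0], marker[1], 8.0, 4.0) if marker else None
    )
    return pk.CentrioleMeasurement(
        id="x", view="side", extents=extents,
        length_nm={"tubulin": tub[1] - tub[0]},
    )


class TestRelativePosition:
    def test_marker_at_tubulin_start(self):
        rec = pk.relative_position(_side_measurement((100, 500), (100, 200)), "marker")
        assert rec.marker_start_rel_nm == pytest.approx(0.0)
        assert rec.marker_end_rel_nm == pytest.approx(100.0)

    def test_shift_invariance(self):
        r0 = pk.relative_position(_side_measurement((100, 500), (120, 260)), "marker")
        r1 = pk.relative_position(_side_measurement((137, 537), (157, 297)), "marker")
        assert r1.marker_start_rel_nm == pytest.approx(r0.marker_start_rel_nm)
        assert r1.marker_end_rel_nm == pytest.approx(r0.marker_end_rel_nm)

    def test_marker_capping_below_wall_gives_negative_start(self):
        rec = pk.relative_position(_side_measurement((100, 500), (80, 190)), "marker")
        assert rec.marker_start_rel_nm == pytest.approx(-20.0)
        assert rec.marker_end_rel_nm == pytest.approx(90.0)

    def test_bottom_view_rejected(self):
        m = pk.CentrioleMeasurement(
            id="x", view="bottom",
            extents={"tubulin": pk.SignalExtent("tubulin", 0, 10, 1, 0.5)},
        )
        with pytest.raises(ValueError, match="side-view"):
            pk.relative_position(m, "marker")


class TestSummarizePositions:
    def test_hand_arithmetic(self):
        recs = [
            pk.RelativePositionRecord(300, 0.0, 100.0, True),
            pk.RelativePositionRecord(350, 0.0, 120.0, True),
        ]
        s = pk.summarize_positions(recs)
        assert s.mean_start_nm == pytest.approx(0.0)
        assert s.sd_start_nm == pytest.approx(0.0)
        assert s.mean_end_nm == pytest.approx(110.0)
        # sample sd (n-1): sqrt(((100-110)^2+(120-110)^2)/1)
        assert s.sd_end_nm == pytest.approx(np.sqrt(200.0))

    def test_single_record_flagged_with_zero_sd(self):
        s = pk.summarize_positions([pk.RelativePositionRecord(300, 5.0, 90.0, True)])
        assert s.single_record
        assert s.sd_start_nm == 0.0
        assert s.mean_end_nm == pytest.approx(90.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(11)
        recs = [
            pk.RelativePositionRecord(float(L), float(a), float(a + 50), True)
            for L, a in zip(rng.uniform(100, 400, 10), rng.uniform(-20, 20, 10))
        ]
        s0 = pk.summarize_positions(recs)
        s1 = pk.summarize_positions(list(reversed(recs)))
        assert s1.mean_start_nm == pytest.approx(s0.mean_start_nm)
        assert s1.sd_end_nm == pytest.approx(s0.sd_end_nm)
        np.testing.assert_allclose(
            s1.curve["tubulin_length_nm"], s0.curve["tubulin_length_nm"]
        )

    def test_no_present_records_is_an_error(self):
        with pytest.raises(ValueError, match="present"):
            pk.summarize_positions([pk.RelativePositionRecord(300, None, None, False)])

    def test_binned_curve(self):
        recs = [
            pk.RelativePositionRecord(float(L), 0.0, float(L) / 2, True)
            for L in (100, 110, 190, 210)
        ]
        s = pk.summarize_positions(recs, bin_width_nm=100.0)
        assert s.binned is not None
        assert len(s.binned) == 2
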