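"""Simulator unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pccr.detect import Frame, PupilTracker, DetectionConfig
from pccr.simulate import (
    EyeStateTruth,
    OpticalConfig,
    Protocol,
    Segment,
    cr_displacement,
    minimum_jerk,
    pupil_response,
    render_eye_frame,
    simulate_protocol,
    vergence_from_distance,
)


class TestOpticalConfig:
    def test_derived_pixel_pitch(self):
        cfg = OpticalConfig()
        assert cfg.um_per_px == pytest.approx(1000 / 39.7)
        assert round(cfg.um_per_px, 1) == 25.2

    def test_arcmin_per_pixel(self):
        assert round(OpticalConfig().arcmin_per_px, 1) == 18.1

    @pytest.mark.parametrize("kw", [
        {"magnification": 0.0},
        {"frame_rate": -1.0},
        {"ipd_mm": 0.0},
        {"background_grey": 10.0},       # below pupil grey
        {"cr_grey": 240.0},              # not above the CR threshold
        {"pupil_grey": -5.0},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            OpticalConfig(**kw)


class TestVergenceFromDistance:
    def test_infinity_is_parallel(self):
        assert vergence_from_distance(1e12) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("distance, printed", [
        (540.0, 6.360), (290.0, 11.812),
    ])
    def test_printed_values_exact(self, distance, printed):
        assert round(vergence_from_distance(distance), 3) == printed

    @pytest.mark.parametrize("distance, printed", [
        (490.0, 7.008), (440.0, 7.800),
    ])
    def test_printed_values_last_digit(self, distance, printed):
        # the published rounding differs from the closed form by one unit
        # in the third decimal for these two distances
        assert vergence_from_distance(distance) == pytest.approx(printed, abs=1.5e-3)

    def test_strictly_decreasing(self):
        d = np.linspace(100, 5000, 200)
        v = vergence_from_distance(d)
        assert np.all(np.diff(v) < 0)

    @pytest.mark.parametrize("bad", [0.0, -10.0])
    def test_nonpositive_distance_rejected(self, bad):
        with pytest.raises(ValueError):
            vergence_from_distance(bad)


class TestCrDisplacement:
    def test_zero(self):
        assert cr_displacement(0.0) == 0.0

    def test_one_degree_83_um(self):
        assert cr_displacement(1.0) * 1000 == pytest.approx(83.3, abs=0.05)

    def test_one_arcmin_1p39_um(self):
        assert round(cr_displacement(1 / 60) * 1000, 2) == 1.39

    @given(st.floats(-30, 30), st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_linear_and_odd(self, a, b):
        assert cr_displacement(a + b) == pytest.approx(
            cr_displacement(a) + cr_displacement(b), abs=1e-12)
        assert cr_displacement(-a) == pytest.approx(-cr_displacement(a), abs=1e-12)


class TestPupilResponse:
    def test_before_latency(self):
        assert pupil_response(0.1, 6, 4, 0.25, 0.4) == 6.0

    def test_asymptote(self):
        assert pupil_response(100.0, 6, 4, 0.25, 0.4) == pytest.approx(4.0)

    def test_one_tau_closed_form(self):
        got = pupil_response(0.25 + 0.4, 6, 4, 0.25, 0.4)
        assert got == pytest.approx(6 - (1 - math.exp(-1)) * 2)

    def test_relaxes_back_after_offset(self):
        late = pupil_response(10.0, 6, 4, 0.25, 0.4, stim_duration=0.5)
        assert late == pytest.approx(6.0, abs=1e-6)

    def test_continuous_at_offset(self):
        eps = 1e-6
        before = pupil_response(0.75 - eps, 6, 4, 0.25, 0.4, stim_duration=0.5)
        after = pupil_response(0.75 + eps, 6, 4, 0.25, 0.4, stim_duration=0.5)
        assert before == pytest.approx(after, abs=1e-4)

    @pytest.mark.parametrize("args", [(4, 6, 0.25, 0.4), (6, 4, 0.25, -1.0)])
    def test_invalid_parameters(self, args):
        with pytest.raises(ValueError):
            pupil_response(1.0, *args)


def test_minimum_jerk_endpoints():
    assert minimum_jerk(0.0) == 0.0
    assert minimum_jerk(1.0) == 1.0
    tau = np.linspace(0, 1, 50)
    assert np.all(np.diff(minimum_jerk(tau)) >= 0)


class TestRenderEyeFrame:
    def test_noiseless_centroid_exact(self, noiseless_cfg):
        truth = EyeStateTruth(0, "left", 0, 0, 4.0)
        img, meta = render_eye_frame(truth, noiseless_cfg, 0)
        det = PupilTracker().detect_frame(Frame(img))
        assert det.valid
        assert det.pupil_center == pytest.approx(meta["pupil_center_px"], abs=0.05)
        assert det.cr_center == pytest.approx(meta["cr_center_px"], abs=0.05)

    @pytest.mark.parametrize("diameter", [2.0, 4.0, 6.0, 8.0])
    def test_pupil_pixel_count_matches_disc_area(self, diameter):
        # pupil-only render: the CR disc would carve a hole in the count
        cfg = OpticalConfig(noise_sd=0, gradient_sd=0, cr_diameter_mm=0.0)
        truth = EyeStateTruth(0, "left", 0, 0, diameter)
        img, _ = render_eye_frame(truth, cfg, 0)
        dark = int((img < 0.6 * img.mean()).sum())
        analytic = math.pi * (diameter * cfg.magnification / 2) ** 2
        assert dark == pytest.approx(analytic, rel=0.01)

    def test_four_mm_pupil_about_20k_dark_pixels(self):
        cfg = OpticalConfig(noise_sd=0, gradient_sd=0, cr_diameter_mm=0.0)
        img, _ = render_eye_frame(EyeStateTruth(0, "left", 0, 0, 4.0), cfg, 0)
        dark = int((img < 0.6 * img.mean()).sum())
        assert round(dark, -3) == 20000

    def test_full_occlusion_no_dark_pixels(self, noiseless_cfg):
        truth = EyeStateTruth(0, "left", 0, 0, 4.0, eyelid_aperture=0.0)
        img, _ = render_eye_frame(truth, noiseless_cfg, 0)
        assert int((img < 0.6 * img.mean()).sum()) == 0

    def test_one_degree_moves_cr_3p3_px(self, noiseless_cfg):
        imgs = {}
        for g in (0.0, 1.0):
            truth = EyeStateTruth(0, "left", g, 0, 4.0)
            img, _ = render_eye_frame(truth, noiseless_cfg, 0)
            d = PupilTracker().detect_frame(Frame(img))
            imgs[g] = np.array(d.cr_center) - np.array(d.pupil_center)
        dx = imgs[1.0][0] - imgs[0.0][0]
        assert dx == pytest.approx(0.0833 * 39.7, abs=0.1)

    def test_out_of_bounds_flagged_but_rendered(self, noiseless_cfg):
        truth = EyeStateTruth(0, "left", 0, 0, 4.0, pupil_center_offset_mm=9.0)
        img, meta = render_eye_frame(truth, noiseless_cfg, 0)
        assert img.shape == noiseless_cfg.frame_shape
        assert not meta["pupil_in_bounds"]

    def test_determinism(self, default_cfg):
        truth = EyeStateTruth(0, "left", 1.0, -0.5, 4.0)
        a, _ = render_eye_frame(truth, default_cfg, 42)
        b, _ = render_eye_frame(truth, default_cfg, 42)
        c, _ = render_eye_frame(truth, default_cfg, 43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("gaze", [(-10, 0), (-5, 3), (0, 0), (4, -4), (10, 5)])
    def test_geometry_round_trip(self, noiseless_cfg, gaze):
        gh, gv = gaze
        truth = EyeStateTruth(0, "left", gh, gv, 5.0)
        img, _ = render_eye_frame(truth, noiseless_cfg, 0)
        det = PupilTracker().detect_frame(Frame(img))
        k = noiseless_cfg.deg_per_px
        est_h = (det.cr_center[0] - det.pupil_center[0]) * k
        est_v = (det.pupil_center[1] - det.cr_center[1]) * k
        assert est_h == pytest.approx(gh, abs=0.05)
        assert est_v == pytest.approx(gv, abs=0.05)


class TestEyeStateTruth:
    @pytest.mark.parametrize("kw", [
        {"pupil_diameter_mm": 0.0},
        {"pupil_diameter_mm": 12.0},
        {"eyelid_aperture": 1.5},
        {"eye": "middle"},
    ])
    def test_invariants(self, kw):
        base = dict(frame_index=0, eye="left", gaze_h=0, gaze_v=0,
                    pupil_diameter_mm=4.0)
        base.update(kw)
        with pytest.raises(ValueError):
            EyeStateTruth(**base)


class TestSimulateProtocol:
    def test_static_target_constant_truth(self, noiseless_cfg):
        sim = simulate_protocol(Protocol([Segment(50, 30, -20)]),
                                noiseless_cfg, 0)
        for eye in ("left", "right"):
            t = sim.truth_for(eye)
            assert t["gaze_h_deg"].nunique() == 1
            assert t["gaze_v_deg"].nunique() == 1

    def test_depth_alternation_vergence(self, noiseless_cfg):
        segs = [Segment(40, target_distance_mm=540.0),
                Segment(40, target_distance_mm=290.0)]
        sim = simulate_protocol(Protocol(segs), noiseless_cfg, 0)
        t = sim.truth_for("left")
        far = t.loc[t["segment"] == 0, "vergence_deg"].iloc[-1]
        near = t.loc[t["segment"] == 1, "vergence_deg"].iloc[-1]
        assert round(far, 3) == 6.360
        assert round(near, 3) == 11.812

    def test_light_step_constricts_after_latency(self, noiseless_cfg):
        fs = noiseless_cfg.frame_rate
        segs = [Segment(int(fs), screen_grey=0),
                Segment(30, screen_grey=150),
                Segment(int(fs), screen_grey=0)]
        sim = simulate_protocol(Protocol(segs), noiseless_cfg, 0)
        p = sim.truth_for("left")["pupil_mm"].to_numpy()
        onset = int(fs)
        latency_frames = int(round(noiseless_cfg.pupil_latency_s * fs))
        assert p[onset + latency_frames - 2] == pytest.approx(
            noiseless_cfg.pupil_baseline_mm, abs=1e-6)
        assert p[onset + latency_frames + 20] < noiseless_cfg.pupil_baseline_mm - 0.05

    def test_truth_log_deterministic_and_aligned(self, default_cfg):
        protocol = Protocol([Segment(20, 0, 0), Segment(20, 50, 0)])
        a = simulate_protocol(protocol, default_cfg, 9)
        b = simulate_protocol(protocol, default_cfg, 9)
        assert a.truth.equals(b.truth)
        fa = next(iter(a.frames("right")))
        fb = next(iter(b.frames("right")))
        assert np.array_equal(fa.image, fb.image)
        assert len(a.truth) == 2 * protocol.n_frames

    def test_target_outside_field_names_segment(self, noiseless_cfg):
        seg = Segment(10, target_x_px=2500, label="way_out")
        with pytest.raises(ValueError, match="way_out"):
            simulate_protocol(Protocol([Segment(10, 0, 0), seg]), noiseless_cfg, 0)

    def test_blink_profile_and_flag(self, noiseless_cfg):
        sim = simulate_protocol(Protocol([Segment(200, 0, 0, blinks=(50,))]),
                                noiseless_cfg, 0)
        t = sim.truth_for("left")
        ap = t["eyelid_aperture"].to_numpy()
        blink = t["blink"].to_numpy()
        assert ap.min() == pytest.approx(0.0, abs=0.05)
        assert blink.any()
        assert np.array_equal(blink,
                              ap < noiseless_cfg.blink_aperture_threshold)
        assert not blink[:40].any() and not blink[-40:].any()

    def test_ttl_marks_new_targets(self, noiseless_cfg):
        sim = simulate_protocol(Protocol([Segment(30, 0, 0), Segment(30, 40, 0)]),
                                noiseless_cfg, 0)
        ttl = sim.truth_for("left")["ttl"].to_numpy()
        assert list(np.where(ttl == 1)[0]) == [0, 30]

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            Protocol([])
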