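"""2D gait features: normalization, strike detection, spatiotemporal measures, MOS."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitscore.config import StepDetectionConfig, XcomParams
from gaitscore.gait2d import (
    ankle_vertical_velocity,
    cadence,
    coefficient_of_variation,
    detect_foot_strikes,
    extract_features_2d,
    hip_relative_normalized,
    margin_of_stability,
    normalize_by_hip_distance,
    step_width_series,
    symmetry_index,
)
from gaitscore.io_types import FootStrikeSeries
from gaitscore.synthetic_data import GaitParams, simulate_bout
from tests.conftest import make_static_bout_2d


class TestNormalization:
    def test_unit_hip_distance_is_identity(self):
        bout = make_static_bout_2d(hip_half=0.5)  # hip distance exactly 1 px
        norm = normalize_by_hip_distance(bout)
        np.testing.assert_allclose(norm.data["l_ankle"], bout.data["l_ankle"])

    def test_resolution_invariance(self, clean_walk_2d):
        bout, _ = clean_walk_2d
        double = bout.copy_with({k: v * 2.0 for k, v in bout.data.items()})
        n1 = normalize_by_hip_distance(bout)
        n2 = normalize_by_hip_distance(double)
        np.testing.assert_allclose(n1.data["l_ankle"], n2.data["l_ankle"], rtol=1e-12)

    def test_coincident_hips_marked_unusable(self):
        bout = make_static_bout_2d(hip_half=0.0)
        norm = normalize_by_hip_distance(bout)
        assert np.isnan(norm.data["l_ankle"]).all()

    def test_hip_relative_is_translation_invariant(self, clean_walk_2d):
        bout, _ = clean_walk_2d
        shifted = bout.copy_with({k: v + np.array([123.0, -77.0]) for k, v in bout.data.items()})
        a = hip_relative_normalized(bout)
        b = hip_relative_normalized(shifted)
        np.testing.assert_allclose(a.data["l_ankle"], b.data["l_ankle"], rtol=1e-9)


class TestAnkleVelocity:
    def test_constant_height_zero_velocity(self, static_bout_2d, det_cfg):
        v = ankle_vertical_velocity(static_bout_2d, "left", det_cfg)
        np.testing.assert_allclose(v[np.isfinite(v)], 0.0, atol=1e-9)

    def test_sinusoid_matches_analytic_derivative(self):
        # ankle height sin(2*pi*t) in normalized units: hips 1 px apart and
        # fixed, so the pelvis-referenced normalized height equals -v_ankle
        bout = make_static_bout_2d(n_frames=120, hip_half=0.5)
        t = np.arange(120) / 30.0
        bout.data["l_ankle"] = np.column_stack([np.full(120, 960.0), 540.0 - np.sin(2 * np.pi * t)])
        cfg = StepDetectionConfig(smoothing_window=1)
        v = ankle_vertical_velocity(bout, "left", cfg)
        expect = 2 * np.pi * np.cos(2 * np.pi * t)
        err = np.abs(v[1:-1] - expect[1:-1]).max()
        assert err < 0.01 * 2 * np.pi

    def test_single_usable_frame_is_error(self, det_cfg):
        bout = make_static_bout_2d(n_frames=30)
        bout.data["l_ankle"][1:] = np.nan
        with pytest.raises(ValueError):
            ankle_vertical_velocity(bout, "left", det_cfg)


class TestStrikeDetection:
    def test_counts_and_alternation_noise_free(self, det_cfg):
        params = GaitParams(cadence=105, n_steps=10, step_time_cv=0.0)
        bout, truth = simulate_bout(params, "2d", seed=2)
        strikes = detect_foot_strikes(bout, det_cfg)
        assert strikes.n_strikes == 10
        assert strikes.sides == truth.strike_sides
        err_frames = np.abs(strikes.times - truth.strike_times) * 30.0
        assert err_frames.max() < 1.0

    def test_stationary_pose_no_strikes(self, static_bout_2d, det_cfg):
        assert detect_foot_strikes(static_bout_2d, det_cfg).n_strikes == 0

    def test_scale_invariant_strike_times(self, clean_walk_2d, det_cfg):
        bout, _ = clean_walk_2d
        scaled = bout.copy_with({k: v * 3.0 for k, v in bout.data.items()})
        s1 = detect_foot_strikes(bout, det_cfg)
        s2 = detect_foot_strikes(scaled, det_cfg)
        np.testing.assert_allclose(s1.times, s2.times, rtol=1e-9)

    def test_noisy_count_error_bounded(self, det_cfg):
        errors = []
        for seed in range(10):
            params = GaitParams(cadence=100, n_steps=10, step_time_cv=0.04, keypoint_noise_sd=0.05)
            bout, _ = simulate_bout(params, "2d", seed=seed)
            errors.append(abs(detect_foot_strikes(bout, det_cfg).n_strikes - 10))
        assert max(errors) <= 1


class TestSpatiotemporal:
    def test_cadence_arithmetic(self):
        # eleven strikes spanning 6 s = ten steps per 6 s -> 100 steps/min
        times = np.linspace(0.0, 6.0, 11)
        sides = tuple("left" if i % 2 == 0 else "right" for i in range(11))
        assert cadence(FootStrikeSeries(times=times, sides=sides)) == pytest.approx(100.0)

    def test_cadence_single_strike_missing(self):
        s = FootStrikeSeries(times=np.array([1.0]), sides=("left",))
        assert np.isnan(cadence(s))

    def test_cadence_recovery(self, det_cfg):
        params = GaitParams(cadence=110, n_steps=10, step_time_cv=0.0)
        bout, _ = simulate_bout(params, "2d", seed=4)
        f = extract_features_2d(bout, det_cfg)
        assert abs(f.cadence - 110) < 2.0

    def test_symmetry_index_formula(self):
        assert symmetry_index([0.5, 0.5], [0.5]) == pytest.approx(0.0)
        # |0.5-0.6| / 0.55 * 100
        assert symmetry_index([0.5], [0.6]) == pytest.approx(100 * 0.1 / 0.55)
        with pytest.raises(ValueError):
            symmetry_index([], [0.5])

    @given(
        left=st.lists(st.floats(0.3, 2.0), min_size=1, max_size=8),
        right=st.lists(st.floats(0.3, 2.0), min_size=1, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_symmetry_index_swap_invariant_nonnegative(self, left, right):
        si = symmetry_index(left, right)
        assert si >= 0.0
        assert si == pytest.approx(symmetry_index(right, left))

    def test_cv_formula_and_degenerate(self):
        assert coefficient_of_variation([1.0, 2.0, 3.0]) == pytest.approx(0.5)
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == pytest.approx(0.0)
        assert np.isnan(coefficient_of_variation([1.0]))
        assert np.isnan(coefficient_of_variation([-1.0, 1.0]))

    @given(
        vals=st.lists(st.floats(0.1, 5.0), min_size=2, max_size=10),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_cv_scale_invariant(self, vals, scale):
        v = np.asarray(vals)
        if v.mean() < 1e-6:
            return
        assert coefficient_of_variation(v * scale) == pytest.approx(
            coefficient_of_variation(v), rel=1e-9, abs=1e-12
        )


class TestStepWidth:
    def test_constant_separation(self, det_cfg):
        bout = make_static_bout_2d(hip_half=50.0)  # ankles 100 px apart = 1 hip-width
        times = np.arange(1, 5) * 0.4
        sides = ("left", "right", "left", "right")
        widths = step_width_series(bout, FootStrikeSeries(times=times, sides=sides), det_cfg)
        np.testing.assert_allclose(widths, 1.0, rtol=1e-9)

    def test_generator_width_recovered(self, det_cfg):
        params = GaitParams(step_width=0.12, n_steps=10, step_time_cv=0.0)
        bout, _ = simulate_bout(params, "2d", seed=6)
        strikes = detect_foot_strikes(bout, det_cfg)
        widths = step_width_series(bout, strikes, det_cfg)
        # hip-width units -> metres via the template's 0.30 m pelvis
        assert abs(np.nanmean(widths) * 0.30 - 0.12) / 0.12 < 0.10

    def test_too_few_strikes_empty(self, static_bout_2d, det_cfg):
        s = FootStrikeSeries(times=np.array([1.0]), sides=("left",))
        assert step_width_series(static_bout_2d, s, det_cfg).size == 0


def brute_force_mos(bout, strikes, p, cfg):
    """Independent frame-by-frame margin-of-stability recomputation."""
    from gaitscore.gait2d import _hip_scale
    from gaitscore._events import estimate_velocity

    fs = bout.frame_rate
    scale = _hip_scale(bout, cfg.reference_window)
    lhip, rhip = bout.joint("l_hip"), bout.joint("r_hip")
    centre = (lhip + rhip) / 2.0
    la = (bout.joint("l_ankle") - centre) * np.array([1.0, -1.0]) / scale[:, None]
    ra = (bout.joint("r_ankle") - centre) * np.array([1.0, -1.0]) / scale[:, None]
    vel_u = estimate_velocity(centre[:, 0], fs, cfg.smoothing_window) / scale
    vla = estimate_velocity(la[:, 1], fs, cfg.smoothing_window)
    vra = estimate_velocity(ra[:, 1], fs, cfg.smoothing_window)
    frames = np.clip(np.round(strikes.times * fs).astype(int), 0, bout.n_frames - 1)
    mos = np.full(bout.n_frames, np.nan)
    for i in range(bout.n_frames):
        if abs(vla[i]) <= abs(vra[i]):
            ankle_u = la[i, 0]
        else:
            ankle_u = ra[i, 0]
        xcom = p.velocity_scale * vel_u[i]
        outward = 1.0 if ankle_u >= 0 else -1.0
        mos[i] = outward * (ankle_u - xcom)
    window = mos[frames[0] : frames[-1] + 1]
    avg = np.nanmean(np.abs(window))
    minima = []
    for a, b in zip(frames[:-1], frames[1:]):
        seg = mos[a : b + 1]
        if np.isfinite(seg).any():
            minima.append(np.nanmin(seg))
    return avg, float(np.mean(minima))


class TestMarginOfStability:
    def test_balanced_static_stance_zero(self, det_cfg):
        bout = make_static_bout_2d(ankle_du=-50.0)  # left ankle under hip centre
        bout.data["r_ankle"][:, 1] += 30.0  # right foot raised: left is stance
        s = FootStrikeSeries(times=np.array([0.5, 1.0, 1.5]), sides=("left", "right", "left"))
        avg, _ = margin_of_stability(bout, s, XcomParams(velocity_scale=0.0), det_cfg)
        assert avg == pytest.approx(0.0, abs=1e-9)

    def test_constant_offset(self, det_cfg):
        # stance ankle 0.4 hip-widths lateral of the hip centre, zero velocity
        bout = make_static_bout_2d(ankle_du=0.0)
        bout.data["l_ankle"][:, 0] = 960.0 + 40.0
        bout.data["r_ankle"][:, 0] = 960.0 + 40.0
        s = FootStrikeSeries(times=np.array([0.5, 1.0, 1.5]), sides=("left", "right", "left"))
        avg, avg_min = margin_of_stability(bout, s, XcomParams(velocity_scale=0.0), det_cfg)
        assert avg == pytest.approx(0.4, abs=1e-9)
        assert avg_min == pytest.approx(0.4, abs=1e-9)

    def test_matches_brute_force_oracle(self, det_cfg):
        p = XcomParams()
        rng = np.random.default_rng(0)
        for seed in rng.integers(0, 10_000, size=25):
            params = GaitParams(
                cadence=float(rng.uniform(90, 120)),
                n_steps=8,
                step_time_cv=0.03,
                keypoint_noise_sd=0.02,
            )
            bout, _ = simulate_bout(params, "2d", seed=int(seed))
            strikes = detect_foot_strikes(bout, det_cfg)
            if strikes.n_strikes < 2:
                continue
            got = margin_of_stability(bout, strikes, p, det_cfg)
            want = brute_force_mos(bout, strikes, p, det_cfg)
            np.testing.assert_allclose(got, want, rtol=1e-9)


class TestExtractFeatures2D:
    def test_step_count_matches_generator(self, det_cfg):
        bout, _ = simulate_bout(GaitParams(n_steps=8, step_time_cv=0.0), "2d", seed=9)
        f = extract_features_2d(bout, det_cfg)
        assert f.steps_of_walk == 8

    def test_all_features_invariant_to_scaling(self, clean_walk_2d, det_cfg):
        bout, _ = clean_walk_2d
        scaled = bout.copy_with({k: v * 2.0 + np.array([50.0, -20.0]) for k, v in bout.data.items()})
        f1 = extract_features_2d(bout, det_cfg)
        f2 = extract_features_2d(scaled, det_cfg)
        for k, v in f1.as_dict().items():
            assert f2.as_dict()[k] == pytest.approx(v, rel=1e-9), k

    def test_perspective_distance_nearly_cancelled(self, det_cfg):
        params = GaitParams(n_steps=8, step_time_cv=0.0)
        near, _ = simulate_bout(params, "2d", seed=5)
        far, _ = simulate_bout(params, "2d", seed=5, camera_distance_extra=8.0)
        f_near = extract_features_2d(near, det_cfg)
        f_far = extract_features_2d(far, det_cfg)
        assert f_far.steps_of_walk == f_near.steps_of_walk
        assert f_far.cadence == pytest.approx(f_near.cadence, rel=0.02)
        assert f_far.avg_step_width == pytest.approx(f_near.avg_step_width, rel=0.05)
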