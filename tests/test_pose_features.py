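"""Tests for pose-feature computation on keypoint tracks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifespan_architect.pose_features import (
    BODY_CHAIN,
    KEYPOINTS,
    KeypointTrack,
    PoseConfig,
    assemble_features,
    compute_angles,
    compute_dispersion,
    compute_geometry,
    compute_kinematics,
    detect_reversal,
    linear_separability,
    minimum_enclosing_circle_area,
    reduce_to_pcs,
    score_sleep,
)
from lifespan_architect.synthetic_data import BehaviorProgram, SimConfig, simulate_track


def make_track(snout_xy: np.ndarray, heading: np.ndarray | None = None,
               tank=(500.0, 500.0), fps=20.0) -> KeypointTrack:
    """Straight-bodied track with the snout on a given path."""
    T = len(snout_xy)
    if heading is None:
        heading = np.tile([1.0, 0.0], (T, 1))
    cum = np.array([10.0, 20.0, 30.0, 38.0])
    data = {"frame": np.arange(T), "timestamp": np.arange(T) / fps}
    pts = {
        "snout": snout_xy,
        "midbody": snout_xy - cum[0] * heading,
        "endbody": snout_xy - cum[1] * heading,
        "tail": snout_xy - cum[2] * heading,
        "fan": snout_xy - cum[3] * heading,
        "sidebody": snout_xy - cum[0] * heading + 5.0,
    }
    for kp in KEYPOINTS:
        data[f"x_{kp}"] = pts[kp][:, 0]
        data[f"y_{kp}"] = pts[kp][:, 1]
        data[f"vis_{kp}"] = np.ones(T, dtype=bool)
    return KeypointTrack(df=pd.DataFrame(data), tank_size=tank)


IDENTITY_FILTER = PoseConfig(filter_b=(1.0,), filter_a=(1.0,))


class TestKinematics:
    def test_stationary_track_zero_velocity(self):
        track = make_track(np.tile([100.0, 100.0], (50, 1)))
        kin = compute_kinematics(track, IDENTITY_FILTER)
        assert np.allclose(kin.speeds.iloc[1:].to_numpy(), 0.0)

    def test_constant_advance_speed_and_heading(self):
        # 5 px/frame at 20 fps along +x -> 100 px/s, heading (1, 0)
        xs = 50.0 + 5.0 * np.arange(40)
        track = make_track(np.column_stack([xs, np.full(40, 100.0)]))
        kin = compute_kinematics(track, IDENTITY_FILTER)
        assert np.allclose(kin.speeds["snout_velocity"].iloc[1:], 100.0)
        assert np.allclose(kin.heading_vec, [1.0, 0.0])

    def test_filtered_velocity_matches_convolution_oracle(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(size=60))
        track = make_track(np.column_stack([100 + x, np.full(60, 100.0)]))
        config = PoseConfig()  # 5-tap moving average
        kin = compute_kinematics(track, config)
        b = np.asarray(config.filter_b)
        # filtering commutes with differencing for an LTI filter, so the
        # filtered velocity equals the kernel convolved with the raw
        # difference sequence (zero-padded before recording start)
        d = np.diff(100 + x)
        vel_oracle = np.convolve(b, d)[: len(d)] * 20.0
        got = kin.speeds["snout_velocity"].iloc[1:].to_numpy()
        assert np.allclose(got, np.abs(vel_oracle), atol=1e-6)

    def test_single_frame_all_missing_with_warning(self):
        track = make_track(np.array([[10.0, 10.0]]))
        with pytest.warns(UserWarning, match="single-frame"):
            kin = compute_kinematics(track, IDENTITY_FILTER)
        assert kin.speeds.isna().all().all()


class TestDispersion:
    def test_stationary_snout_zero_dispersion(self):
        disp = compute_dispersion(np.tile([50.0, 50.0], (100, 1)), PoseConfig())
        assert np.allclose(disp, 0.0)

    def test_known_span_area(self):
        # snout spans dx=10, dy=0 -> area = pi * (100/4) = 25 pi
        xy = np.tile([50.0, 50.0], (40, 1))
        xy[20, 0] = 60.0
        disp = compute_dispersion(xy, PoseConfig())
        assert np.isclose(disp[-1], 25.0 * np.pi)

    def test_rectangle_corners_match_enclosing_circle(self):
        # 6 x 8 rectangle: diagonal 10, radius 5 -> area 25 pi, equal to the
        # exact minimum enclosing circle of a rectangle
        corners = np.array([[0.0, 0.0], [6.0, 0.0], [6.0, 8.0], [0.0, 8.0]])
        xy = np.tile(corners, (10, 1))
        disp = compute_dispersion(xy, PoseConfig())
        assert np.isclose(disp[-1], 25.0 * np.pi)
        assert np.isclose(minimum_enclosing_circle_area(corners), 25.0 * np.pi)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bbox_circle_bounds_minimum_enclosing_circle(self, seed):
        pts = np.random.default_rng(seed).uniform(0, 100, size=(12, 2))
        disp = compute_dispersion(pts, PoseConfig(dispersion_window=12))
        assert disp[-1] >= minimum_enclosing_circle_area(pts) - 1e-9

    def test_translation_and_rotation_invariance(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(10, 90, size=(60, 2))
        base = compute_dispersion(xy, PoseConfig())
        shifted = compute_dispersion(xy + [37.0, -11.0], PoseConfig())
        rotated = compute_dispersion(xy[:, ::-1] * [1, -1], PoseConfig())  # 90 deg
        assert np.allclose(base, shifted)
        assert np.allclose(base, rotated)


class TestGeometry:
    def test_straight_body_length_and_counts(self):
        track = make_track(np.tile([100.0, 100.0], (10, 1)))
        geom = compute_geometry(track, PoseConfig())
        assert np.allclose(geom["body_length"], 38.0)  # 10+10+10+8
        counts = geom[[f"count_{kp}" for kp in KEYPOINTS]]
        assert np.all(counts.to_numpy() == 1.0)

    def test_snout_edge_distance(self):
        xy = np.tile([3.0, 50.0], (5, 1))
        track = make_track(xy, tank=(100.0, 100.0))
        geom = compute_geometry(track, PoseConfig())
        assert np.allclose(geom["dist_snout"], 3.0)

    def test_tail_fan_proportion(self):
        track = make_track(np.tile([100.0, 100.0], (5, 1)))
        geom = compute_geometry(track, PoseConfig())
        assert np.allclose(geom["tail_fan_prop"], 8.0 / 38.0)


class TestAngles:
    def test_collinear_body_straight_angles(self):
        track = make_track(np.tile([100.0, 100.0], (5, 1)))
        ang = compute_angles(track)
        for col in ("alpha1", "alpha2", "alpha3"):
            assert np.allclose(ang[col], np.pi)
        for col in ("theta1", "theta2", "theta3"):
            assert np.allclose(ang[col], 0.0)
        assert np.allclose(ang["alpha_all"], 3 * np.pi)

    def test_right_angle_at_midbody(self):
        df = make_track(np.tile([100.0, 100.0], (3, 1))).df.copy()
        # bend endbody so snout-midbody-endbody is a right angle
        df["x_endbody"] = df["x_midbody"]
        df["y_endbody"] = df["y_midbody"] - 10.0
        track = KeypointTrack(df=df, tank_size=(500.0, 500.0))
        ang = compute_angles(track)
        assert np.allclose(ang["alpha1"], np.pi / 2)

    def test_left_arc_gives_positive_thetas_and_mirror_flips_sign(self):
        # keypoints on a circle, body curving toward the animal's left
        theta = np.deg2rad([90.0, 70.0, 50.0, 30.0, 10.0])
        r = 50.0
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)]) + 200.0
        T = 4
        data = {"frame": np.arange(T), "timestamp": np.arange(T) / 20.0}
        names = ["snout", "midbody", "endbody", "tail", "fan"]
        for i, kp in enumerate(names):
            data[f"x_{kp}"] = np.full(T, pts[i, 0])
            data[f"y_{kp}"] = np.full(T, pts[i, 1])
            data[f"vis_{kp}"] = np.ones(T, dtype=bool)
        data["x_sidebody"] = np.full(T, pts[1, 0])
        data["y_sidebody"] = np.full(T, pts[1, 1] + 5)
        data["vis_sidebody"] = np.ones(T, dtype=bool)
        track = KeypointTrack(df=pd.DataFrame(data), tank_size=(500.0, 500.0))
        ang = compute_angles(track)
        assert (ang[["theta1", "theta2", "theta3"]].to_numpy() > 0).all()
        # mirror reflection (flip y) reverses the sign convention
        dfm = track.df.copy()
        for kp in KEYPOINTS:
            dfm[f"y_{kp}"] = -dfm[f"y_{kp}"] + 400.0
        angm = compute_angles(KeypointTrack(df=dfm, tank_size=(500.0, 500.0)))
        assert np.allclose(
            angm[["theta1", "theta2", "theta3"]].to_numpy(),
            -ang[["theta1", "theta2", "theta3"]].to_numpy(),
        )
        assert np.allclose(angm["alpha1"], ang["alpha1"])  # alphas unsigned


class TestReversal:
    def test_forward_cruise_positive_dot_no_reversal(self):
        cfg = SimConfig(jitter_sd=0.0, tank_size=(3000.0, 300.0), seed=0)
        track = simulate_track(
            BehaviorProgram([("cruise", 5.0, {})]), cfg, start_xy=(100, 150)
        )
        rev = detect_reversal(track, PoseConfig())
        assert (rev["dot_product"].iloc[1:] > 0).all()
        assert rev["reversal_binary"].sum() == 0

    def test_simulated_reversal_detected_on_interior_frames(self):
        cfg = SimConfig(jitter_sd=0.0, tank_size=(800.0, 600.0), seed=0)
        track = simulate_track(BehaviorProgram([("reversal", 5.0, {})]), cfg)
        rev = detect_reversal(track, PoseConfig())
        assert rev["reversal_binary"].iloc[15:].all()

    def test_velocity_orthogonal_to_heading_zero_dot(self):
        # snout moves along +y while body points along +x
        ys = 100.0 + 2.0 * np.arange(30)
        track = make_track(np.column_stack([np.full(30, 100.0), ys]))
        rev = detect_reversal(track, PoseConfig(rolling_window=1))
        assert np.allclose(rev["dot_product"], 0.0, atol=1e-9)
        assert rev["reversal_binary"].sum() == 0


class TestSleep:
    def test_long_quiet_bout_fully_labeled(self):
        # 90 s below threshold at 20 fps -> all 1800 frames are sleep
        disp = np.full(2400, 100.0)
        disp[300:2100] = 10.0
        sleep = score_sleep(disp, PoseConfig(), fps=20.0)
        assert sleep[300:2100].all()
        assert sleep.sum() == 1800

    def test_short_bout_not_sleep(self):
        disp = np.full(2000, 100.0)
        disp[500:1100] = 10.0  # 30 s
        assert score_sleep(disp, PoseConfig(), fps=20.0).sum() == 0

    def test_missing_dispersion_breaks_run(self):
        disp = np.full(4000, 10.0)
        disp[2000] = np.nan
        sleep = score_sleep(disp, PoseConfig(), fps=20.0)
        assert sleep[:2000].all() and sleep[2001:].all()
        assert not sleep[2000]


class TestAssembleAndPCA:
    def test_exactly_57_columns_one_row_per_frame(self):
        cfg = SimConfig(jitter_sd=0.3, tank_size=(800.0, 600.0), seed=0)
        track = simulate_track(
            BehaviorProgram([("cruise", 3.0, {}), ("rest", 3.0, {})]), cfg
        )
        mat = assemble_features(track, PoseConfig())
        assert mat.features.shape == (len(track), 57)

    def test_constant_base_feature_has_zero_rolling_std(self):
        track = make_track(np.tile([100.0, 100.0], (50, 1)))
        mat = assemble_features(track, PoseConfig())
        assert np.allclose(mat.features["alpha1_std"].iloc[10:], 0.0)

    def test_rank_deficient_data_kills_trailing_pcs(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(300, 2))
        F = pd.DataFrame(base @ rng.normal(size=(2, 8)),
                         columns=[f"f{i}" for i in range(8)])
        from lifespan_architect.pose_features import PoseFeatureMatrix

        red = reduce_to_pcs(PoseFeatureMatrix(features=F), n_pcs=6, smooth_window=1)
        assert red.explained_variance_ratio[2:].max() < 1e-12

    def test_loadings_orthonormal_and_evr_sorted(self):
        rng = np.random.default_rng(1)
        F = pd.DataFrame(rng.normal(size=(400, 10)),
                         columns=[f"f{i}" for i in range(10)])
        from lifespan_architect.pose_features import PoseFeatureMatrix

        red = reduce_to_pcs(PoseFeatureMatrix(features=F), n_pcs=5, smooth_window=1)
        L = red.loadings
        assert np.allclose(L.T @ L, np.eye(5), atol=1e-10)
        assert np.all(np.diff(red.explained_variance_ratio) <= 1e-12)


class TestLinearSeparability:
    def test_separated_clouds_near_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (200, 5)), rng.normal(8, 1, (200, 5))])
        y = np.repeat([0, 1], 200)
        assert linear_separability(X, y) > 0.99

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(400, 5))
        y = rng.permutation(np.repeat([0, 1], 200))
        acc = linear_separability(X, y, seed=1)
        assert 0.4 < acc < 0.6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            linear_separability(np.zeros((10, 5)), np.zeros(10))
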