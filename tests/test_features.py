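"""Feature formulas against independent brute-force oracles, plus the
stated invariances (translation, scale) and class-separation properties."""

from __future__ import annotations

import numpy as np
import pytest

from fnftremor.features import (
    FeatureError,
    SMOOTH_WINDOW,
    MERGE_GAP,
    MIN_RUN,
    compute_accel_variance,
    compute_angular_feature,
    compute_avg_travel_distance,
    compute_histogram_feature,
    compute_rmsd,
    compute_time_ratio,
    default_movement_threshold,
    extract_features,
    segment_round_trips,
)
from fnftremor.synthetic import KinematicsParams, generate_trajectory
from fnftremor.trajectory import FingerTrajectory

from conftest import random_fnf_params
from oracles import (
    accel_variance_oracle,
    angular_count_oracle,
    avg_travel_oracle,
    histogram_feature_oracle,
    quadratic_rmsd_oracle,
    segmentation_oracle,
)


def _traj(x, y, fps=30.0):
    x = np.asarray(x, dtype=float)
    return FingerTrajectory(
        frame_index=np.arange(len(x)),
        x=x,
        y=np.asarray(y, dtype=float),
        valid=np.ones(len(x), bool),
        fps=fps,
    )


def _random_walk(rng, n=60):
    x = np.cumsum(rng.normal(1.0, 2.0, n))
    y = np.cumsum(rng.normal(0.0, 2.0, n))
    return _traj(x, y)


class TestRmsd:
    def test_exact_quadratic_gives_zero(self):
        x = np.linspace(0, 10, 30)
        y = 2 * x**2 + 3 * x + 1
        assert compute_rmsd(_traj(x, y)) == pytest.approx(0.0, abs=1e-9)

    def test_line_is_admissible_quadratic(self):
        x = np.linspace(0, 10, 20)
        assert compute_rmsd(_traj(x, 5 * x - 2)) == pytest.approx(0.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            t = _random_walk(rng, n=20)
            expected = quadratic_rmsd_oracle(t.x, t.y)
            assert compute_rmsd(t) == pytest.approx(expected, rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(FeatureError):
            compute_rmsd(_traj([5, 5, 5, 5], [1, 2, 3, 4]))


class TestAccelVariance:
    def test_constant_velocity_gives_zero(self):
        x = np.arange(20.0) * 3
        assert compute_accel_variance(_traj(x, np.zeros(20))) == 0.0

    def test_known_accelerations(self):
        # speeds 1,2,4,7 -> accelerations 1,2,3 -> population variance 2/3
        x = np.cumsum([0, 1, 2, 4, 7])
        assert compute_accel_variance(_traj(x, np.zeros(5))) == pytest.approx(
            2 / 3, rel=1e-12
        )

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = _random_walk(rng)
            assert compute_accel_variance(t) == pytest.approx(
                accel_variance_oracle(t.x, t.y), rel=1e-9
            )


class TestHistogramFeature:
    def test_uniform_occupancy_gives_zero(self):
        # 4 frames in each quarter of the range
        x = np.concatenate([np.full(4, v) for v in [0.5, 1.5, 2.5, 3.4]])
        t = _traj(x, np.zeros(16))
        assert compute_histogram_feature(t) == 0.0

    def test_piled_bin(self):
        # counts {10,2,2,2}, n=16 -> (10 - 2)/16 = 0.5
        x = np.concatenate(
            [np.full(10, 0.1), np.full(2, 1.5), np.full(2, 2.5), np.full(2, 3.4)]
        )
        assert compute_histogram_feature(_traj(x, np.zeros(16))) == 0.5

    def test_matches_binning_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            t = _random_walk(rng)
            assert compute_histogram_feature(t) == pytest.approx(
                histogram_feature_oracle(t.x, len(t)), abs=1e-12
            )

    def test_constant_x_rejected(self):
        with pytest.raises(FeatureError):
            compute_histogram_feature(_traj([1, 1, 1, 1], [0, 1, 2, 3]))


class TestAngularFeature:
    def test_horizontal_motion_not_counted(self):
        x = np.array([0.0, 1, 2, 1, 0])  # theta = 0 or +/-180
        count, frac = compute_angular_feature(_traj(x, np.zeros(5)))
        assert count == 0 and frac == 0.0

    def test_diagonal_step_counted(self):
        count, _ = compute_angular_feature(_traj([0, 1], [0, 1]))  # 45 deg
        assert count == 1

    def test_zero_displacement_excluded(self):
        count, frac = compute_angular_feature(_traj([0, 0, 1], [0, 0, 1]))
        assert count == 1 and frac == pytest.approx(0.5)

    def test_matches_per_step_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            t = _random_walk(rng)
            count, frac = compute_angular_feature(t)
            assert count == angular_count_oracle(t.x, t.y)
            assert frac == pytest.approx(count / (len(t) - 1))


class TestSegmentation:
    def test_boundaries_near_ground_truth(self):
        truth = generate_trajectory(KinematicsParams(subject_class="healthy"))
        seg = segment_round_trips(truth.trajectory)
        assert len(seg.touch_epochs) == len(truth.touch_epochs)
        for found, expected in zip(seg.touch_epochs, truth.touch_epochs):
            assert abs(found[0] - expected[0]) <= 1
            assert abs(found[1] - expected[1]) <= 1

    def test_stationary_trajectory_fails(self):
        t = _traj(np.full(20, 3.0), np.full(20, 4.0))
        with pytest.raises(FeatureError):
            segment_round_trips(t)

    def test_symmetric_round_trips(self):
        truth = generate_trajectory(
            KinematicsParams(subject_class="healthy", n_cycles=2)
        )
        seg = segment_round_trips(truth.trajectory)
        init = seg.lengths("initial")
        ret = seg.lengths("return")
        assert len(init) == 2 and len(ret) == 2
        assert init[0] == init[1] == ret[0] == ret[1]

    def test_matches_independent_oracle_on_random_recordings(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            traj = generate_trajectory(random_fnf_params(rng)).trajectory
            thr = default_movement_threshold(traj)
            seg = segment_round_trips(traj, thr)
            o_init, o_ret, o_touch = segmentation_oracle(
                list(traj.x), thr, SMOOTH_WINDOW, MERGE_GAP, MIN_RUN
            )
            assert seg.lengths("initial") == o_init
            assert seg.lengths("return") == o_ret
            assert seg.touch_epochs == o_touch


class TestTimeRatio:
    def test_symmetric_paths_give_one(self):
        truth = generate_trajectory(KinematicsParams(subject_class="healthy"))
        seg = segment_round_trips(truth.trajectory)
        assert compute_time_ratio(seg) == pytest.approx(1.0, abs=0.1)

    def test_direct_evaluation(self):
        from fnftremor.features import Segment, SegmentationResult

        seg = SegmentationResult(
            segments=[
                Segment("initial", 0, 29),
                Segment("return", 30, 45),
                Segment("initial", 46, 79),
                Segment("return", 80, 95),
            ],
            touch_epochs=[],
            movement_threshold=1.0,
        )
        # initial lengths {30, 34}, return {16, 16} -> 32/16 = 2.0
        assert compute_time_ratio(seg) == 2.0

    def test_cd_asymmetry_recovered(self):
        ratios = [
            compute_time_ratio(
                segment_round_trips(
                    generate_trajectory(
                        KinematicsParams.for_class("cd", seed=s)
                    ).trajectory
                )
            )
            for s in range(20)
        ]
        assert np.median(ratios) == pytest.approx(1.5, rel=0.10)


class TestAvgTravelDistance:
    def test_still_finger_during_touch_gives_zero(self):
        from fnftremor.features import SegmentationResult

        x = np.concatenate([np.arange(10.0), np.full(6, 9.0), np.arange(9.0)[::-1],
                            np.full(6, 0.0), np.arange(10.0), np.full(6, 9.0)])
        t = _traj(x, np.zeros(len(x)))
        seg = SegmentationResult(
            segments=[], touch_epochs=[(11, 15), (42, 46)], movement_threshold=1.0
        )
        assert compute_avg_travel_distance(t, seg) == 0.0

    def test_constant_displacement_during_touches(self):
        from fnftremor.features import SegmentationResult

        # d_i = 2 for every frame; epochs of 5 frames each -> mean 2.0
        x = np.arange(0.0, 100.0, 2.0)
        t = _traj(x, np.zeros(len(x)))
        seg = SegmentationResult(
            segments=[], touch_epochs=[(10, 14), (30, 34)], movement_threshold=1.0
        )
        assert compute_avg_travel_distance(t, seg) == pytest.approx(2.0)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            traj = generate_trajectory(random_fnf_params(rng)).trajectory
            seg = segment_round_trips(traj)
            if len(seg.touch_epochs) < 2:
                continue
            expected = avg_travel_oracle(
                list(traj.x), list(traj.y), seg.touch_epochs[:2]
            )
            assert compute_avg_travel_distance(traj, seg) == pytest.approx(
                expected, rel=1e-9
            )

    def test_severe_greater_than_mild_et(self):
        wins = 0
        for s in range(20):
            severe = generate_trajectory(
                KinematicsParams.for_class("et", seed=s, tremor_amp_px=15.0)
            )
            mild = generate_trajectory(
                KinematicsParams.for_class("et", seed=s, tremor_amp_px=5.0)
            )
            a = extract_features(severe.trajectory).avg_travel_distance
            b = extract_features(mild.trajectory).avg_travel_distance
            wins += a > b
        assert wins >= 19


class TestExtractFeatures:
    def test_error_names_offending_feature(self):
        t = _traj(np.full(20, 3.0), np.arange(20.0))
        with pytest.raises(FeatureError, match="rmsd"):
            extract_features(t)

    def test_translation_invariance(self):
        truth = generate_trajectory(KinematicsParams.for_class("cd", seed=4))
        t = truth.trajectory
        shifted = t.with_(x=t.x + 37.0, y=t.y - 12.0)
        a = extract_features(t)
        b = extract_features(shifted)
        assert a.to_array() == pytest.approx(b.to_array(), rel=1e-9)

    def test_scale_covariance(self):
        truth = generate_trajectory(KinematicsParams.for_class("et", seed=5))
        t = truth.trajectory
        s = 2.5
        scaled = t.with_(x=t.x * s, y=t.y * s)
        a = extract_features(t)
        b = extract_features(scaled)
        assert b.rmsd == pytest.approx(s * a.rmsd, rel=1e-9)
        assert b.accel_variance == pytest.approx(s**2 * a.accel_variance, rel=1e-9)
        assert b.avg_travel_distance == pytest.approx(
            s * a.avg_travel_distance, rel=1e-9
        )
        assert b.vertical_swing_count == a.vertical_swing_count
        assert b.time_ratio == pytest.approx(a.time_ratio, rel=1e-9)
        assert b.histogram_feature == pytest.approx(a.histogram_feature, rel=1e-9)

    def test_class_separation_medians(self):
        feats = {
            cls: [
                extract_features(
                    generate_trajectory(
                        KinematicsParams.for_class(cls, seed=s)
                    ).trajectory
                )
                for s in range(30)
            ]
            for cls in ("healthy", "et", "cd")
        }
        med = lambda cls, name: np.median([getattr(f, name) for f in feats[cls]])
        assert med("cd", "accel_variance") > med("healthy", "accel_variance")
        assert med("et", "histogram_feature") > med("healthy", "histogram_feature")
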