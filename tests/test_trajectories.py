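import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossloco.errors import (
    DegenerateSeriesError,
    InsufficientGaitError,
    InvalidInputError,
)
from crossloco.trajectories import (
    ForceSeries,
    SpeedSeries,
    Trajectory,
    gait_to_stride_series,
    normalize_series,
    read_manifest,
    read_speed_series,
    read_trajectory,
    resample_to_length,
    segment_trajectory,
    to_speed_series,
    write_manifest,
    write_speed_series,
    write_trajectory,
)
from _oracles import speeds_by_loop, zscore


def _traj(t, x, y, cls=0, dom=0, id="t"):
    return Trajectory(id=id, t=np.array(t, float), x=np.array(x, float),
                      y=np.array(y, float), class_label=cls, domain_label=dom)


class TestTrajectoryInvariants:
    def test_rejects_non_increasing_timestamps(self):
        with pytest.raises(InvalidInputError):
            _traj([0, 1, 1], [0, 1, 2], [0, 0, 0])

    def test_rejects_single_point(self):
        with pytest.raises(InvalidInputError):
            _traj([0], [0], [0])

    def test_rejects_nonbinary_labels(self):
        with pytest.raises(InvalidInputError):
            _traj([0, 1], [0, 1], [0, 0], cls=2)


class TestToSpeedSeries:
    def test_three_four_five(self):
        s = to_speed_series(_traj([0, 1], [0, 3], [0, 4]))
        assert s.values == pytest.approx([5.0])

    def test_no_displacement(self):
        s = to_speed_series(_traj([0, 2], [1, 1], [1, 1]))
        assert s.values == pytest.approx([0.0])

    def test_matches_loop_oracle(self, rng):
        t = np.cumsum(rng.uniform(0.1, 2.0, 10))
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        got = to_speed_series(_traj(t, x, y)).values
        assert np.allclose(got, speeds_by_loop(t, x, y), atol=1e-12)

    def test_labels_carried_and_flag_false(self):
        s = to_speed_series(_traj([0, 1], [0, 1], [0, 0], cls=1, dom=1))
        assert (s.class_label, s.domain_label, s.normalized) == (1, 1, False)

    def test_translation_rotation_invariant(self, rng):
        t = np.arange(12.0)
        x, y = rng.standard_normal(12), rng.standard_normal(12)
        theta, dx, dy = 0.7, 5.0, -3.0
        xr = x * np.cos(theta) - y * np.sin(theta) + dx
        yr = x * np.sin(theta) + y * np.cos(theta) + dy
        a = to_speed_series(_traj(t, x, y)).values
        b = to_speed_series(_traj(t, xr, yr)).values
        assert np.allclose(a, b, atol=1e-9)


class TestNormalizeSeries:
    def test_z_score_example(self):
        s = SpeedSeries(id="s", values=[1, 2, 3], class_label=0,
                        domain_label=0)
        out = normalize_series(s)
        assert np.allclose(out.values, [-1.22474487, 0.0, 1.22474487],
                           atol=1e-6)
        assert out.normalized

    def test_mean_zero_std_one(self, rng):
        s = SpeedSeries(id="s", values=rng.uniform(0, 5, 50),
                        class_label=0, domain_label=0)
        out = normalize_series(s)
        assert abs(out.values.mean()) < 1e-9
        assert abs(out.values.std() - 1.0) < 1e-9

    def test_constant_series_errors(self):
        s = SpeedSeries(id="s", values=[2.0] * 5, class_label=0,
                        domain_label=0)
        with pytest.raises(DegenerateSeriesError):
            normalize_series(s)

    def test_idempotent(self, rng):
        s = SpeedSeries(id="s", values=rng.standard_normal(30),
                        class_label=0, domain_label=0)
        once = normalize_series(s)
        twice = normalize_series(once)
        assert np.allclose(once.values, twice.values, atol=1e-9)

    def test_scale_invariance_after_normalization(self, rng):
        t = np.arange(20.0)
        x, y = np.cumsum(rng.standard_normal(20)), np.cumsum(
            rng.standard_normal(20))
        a = normalize_series(to_speed_series(_traj(t, x, y))).values
        b = normalize_series(
            to_speed_series(_traj(t, 100 * x, 100 * y))).values
        assert np.allclose(a, b, atol=1e-9)


class TestResample:
    def test_identity(self, rng):
        s = SpeedSeries(id="s", values=rng.standard_normal(600),
                        class_label=0, domain_label=0)
        assert np.array_equal(resample_to_length(s, 600).values, s.values)

    def test_even_stride(self):
        s = SpeedSeries(id="s", values=[0, 1, 2, 3, 4, 5], class_label=0,
                        domain_label=0)
        assert resample_to_length(s, 3).values == pytest.approx([0, 2, 4])

    def test_target_one_keeps_first(self, rng):
        s = SpeedSeries(id="s", values=rng.standard_normal(17),
                        class_label=0, domain_label=0)
        assert resample_to_length(s, 1).values == pytest.approx(
            [s.values[0]])

    def test_too_long_target_errors(self):
        s = SpeedSeries(id="s", values=[1.0, 2.0], class_label=0,
                        domain_label=0)
        with pytest.raises(InvalidInputError):
            resample_to_length(s, 3)

    @given(n=st.integers(2, 200), frac=st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_output_length_exact(self, n, frac):
        target = max(1, int(frac * n))
        s = SpeedSeries(id="s", values=np.arange(n, dtype=float),
                        class_label=1, domain_label=1)
        out = resample_to_length(s, target)
        assert len(out) == target
        assert (out.class_label, out.domain_label) == (1, 1)
        # subsampling preserves order
        assert np.all(np.diff(out.values) >= 0)


class TestSegmentation:
    def test_600s_gives_4_segments(self):
        t = np.arange(0, 601.0)
        traj = _traj(t, t, np.zeros_like(t))
        segs = segment_trajectory(traj, 150.0)
        assert len(segs) == 4

    def test_stationary_dropped(self):
        t = np.arange(0, 301.0)
        traj = _traj(t, np.zeros_like(t), np.zeros_like(t))
        assert segment_trajectory(traj, 150.0, min_movement=1.0) == []

    def test_retained_matches_brute_force(self, rng):
        t = np.arange(0, 600.0)
        # moves in the first half, freezes in the second
        x = np.concatenate([np.cumsum(rng.uniform(0.5, 1, 300)),
                            np.full(300, 0.0)])
        x[300:] = x[299]
        y = np.zeros_like(x)
        traj = _traj(t, x, y)
        seg_s, min_mov = 100.0, 5.0
        segs = segment_trajectory(traj, seg_s, min_mov)
        # brute force: windowed path length
        expected = 0
        n_windows = int(traj.duration // seg_s)
        for k in range(n_windows):
            mask = (t >= k * seg_s) & (t < (k + 1) * seg_s)
            if k == n_windows - 1:
                mask |= t == (k + 1) * seg_s
            path = np.hypot(np.diff(x[mask]), np.diff(y[mask])).sum()
            if path >= min_mov:
                expected += 1
        assert len(segs) == expected

    def test_trailing_remainder_dropped(self):
        t = np.arange(0, 130.0)
        traj = _traj(t, t, t)
        assert len(segment_trajectory(traj, 60.0)) == 2

    def test_segment_count_conservation(self, rng):
        t = np.arange(0, 450.0)
        x = np.cumsum(rng.uniform(0, 1, len(t)))
        traj = _traj(t, x, np.zeros_like(t))
        total = int(traj.duration // 100.0)
        kept = len(segment_trajectory(traj, 100.0, min_movement=0.0))
        assert kept == total  # with zero threshold nothing is dropped


class TestGait:
    def _square(self, period, duration, rate, phase=0.0):
        t = np.arange(0, duration, 1.0 / rate)
        return (np.sin(2 * np.pi * (t - phase) / period) > 0).astype(float)

    def test_square_wave_unit_strides(self):
        f = ForceSeries(id="g", left=self._square(1.0, 10, 100),
                        right=self._square(1.0, 10, 100, phase=0.5),
                        rate=100.0)
        s = gait_to_stride_series(f, contact_threshold=0.5)
        assert np.allclose(s.values, 1.0, atol=1e-6)

    def test_alternating_feet_merge_order(self):
        # left contacts at 1,3,5...; right at 2,4,6... -> strides of 2 s
        # interleaved in timestamp order
        rate = 100.0
        n = int(10 * rate)
        left = np.zeros(n)
        right = np.zeros(n)
        left_onsets = [1.0, 3.0, 5.0, 7.0]
        right_onsets = [2.0, 4.0, 6.0, 8.0]
        for on in left_onsets:
            left[int(on * rate): int(on * rate) + 20] = 1.0
        for on in right_onsets:
            right[int(on * rate): int(on * rate) + 20] = 1.0
        f = ForceSeries(id="g", left=left, right=right, rate=rate)
        s = gait_to_stride_series(f, contact_threshold=0.5)
        # event-list oracle: strides recorded at onset 2..of each foot
        events = sorted([(on, 2.0) for on in left_onsets[1:]]
                        + [(on, 2.0) for on in right_onsets[1:]])
        assert len(s) == len(events)
        assert np.allclose(s.values, [v for _, v in events])

    def test_flat_force_errors(self):
        f = ForceSeries(id="g", left=np.zeros(100), right=np.zeros(100),
                        rate=100.0)
        with pytest.raises(InsufficientGaitError):
            gait_to_stride_series(f, contact_threshold=1.0)


class TestIO:
    def test_trajectory_roundtrip(self, tmp_path, rng):
        t = np.arange(10.0)
        traj = _traj(t, rng.standard_normal(10), rng.standard_normal(10),
                     cls=1, dom=0, id="abc")
        p = tmp_path / "tr.csv"
        write_trajectory(traj, p)
        back = read_trajectory(p, "abc", 1, 0)
        assert np.allclose(back.x, traj.x)
        assert np.allclose(back.t, traj.t)

    def test_manifest_roundtrip(self, tmp_path):
        rows = [{"id": "a", "class": 0, "domain": 1, "path": "a.csv"}]
        p = tmp_path / "manifest.csv"
        write_manifest(rows, p)
        back = read_manifest(p)
        assert back[0]["id"] == "a" and back[0]["domain"] == 1

    def test_manifest_missing_column(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,path\na,a.csv\n")
        with pytest.raises(InvalidInputError):
            read_manifest(p)

    def test_speed_series_roundtrip(self, tmp_path, rng):
        s = SpeedSeries(id="xyz", values=rng.standard_normal(25),
                        class_label=1, domain_label=1, normalized=True)
        p = tmp_path / "s.speed.txt"
        write_speed_series(s, p)
        back = read_speed_series(p)
        assert back.id == "xyz" and back.normalized
        assert np.allclose(back.values, s.values, atol=1e-10)
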