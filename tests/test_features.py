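"""Feature-bank correctness: channel algebra, statistics, smoothness metrics vs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsid.core import Placement, SensorRecording, TriaxialSignal
from fsid.features import (
    ACCEL_CHANNELS,
    DegenerateSignalError,
    FeatureVector,
    count_peaks,
    derive_channels,
    extract_cohort_features,
    feature_schema,
    kinematic_features,
    ldlj,
    nmcp,
    power_index,
    rav,
    sparc,
    stat_features,
    task_feature_vector,
)
from fsid.simulate import minimum_jerk_velocity


def _sig(arr, fs=128.0):
    return TriaxialSignal(np.asarray(arr, dtype=float), fs)


def _smooth_random_signal(rng, n=256, fs=128.0, n_modes=6, max_hz=6.0):
    """Band-limited random signal with positive offset (movement-norm-like)."""
    t = np.arange(n) / fs
    x = np.zeros(n)
    for _ in range(n_modes):
        f = rng.uniform(0.3, max_hz)
        x += rng.uniform(0.2, 1.0) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return x - x.min() + 0.5


def _random_speed_profile(rng, fs=128.0):
    """Random superposition of 1-4 minimum-jerk strokes: a movement-speed profile."""
    total = rng.uniform(1.0, 3.0)
    n = int(total * fs)
    t = np.arange(n) / fs
    v = np.zeros(n)
    for _ in range(rng.integers(1, 5)):
        onset = rng.uniform(0, 0.5 * total)
        dur = rng.uniform(0.3 * total, total - onset)
        tau = np.clip((t - onset) / dur, 0, 1)
        v += rng.uniform(0.3, 1.0) * minimum_jerk_velocity(tau) / dur
    return v


class TestDeriveChannels:
    def test_three_four_five_triple(self):
        acc = _sig([[3, 4, 0], [3, 4, 0]])
        gyr = _sig([[0, 0, 0], [0, 0, 0]])
        ch = derive_channels(acc, gyr)
        row = ch.A[0]
        # ax, ay, az, hori=sqrt(y2+z2), coro=sqrt(x2+z2), sagi=sqrt(x2+y2), norm
        np.testing.assert_allclose(row, [3, 4, 0, 4, 3, 5, 5])
        np.testing.assert_allclose(ch.W, 0)

    def test_norm_axis_plane_identities_on_random_data(self, rng):
        xyz = rng.normal(size=(200, 3))
        ch = derive_channels(_sig(xyz), _sig(rng.normal(size=(200, 3))))
        for arr, (ix, ip) in [(ch.A, (0, 3)), (ch.W, (0, 3))]:
            # norm^2 = axis^2 + complementary-plane^2 for each of the three pairings
            for axis, plane in [(0, 3), (1, 4), (2, 5)]:
                np.testing.assert_allclose(
                    arr[:, 6] ** 2, arr[:, axis] ** 2 + arr[:, plane] ** 2, atol=1e-9
                )

    def test_norm_dominates_planes(self, healthy_recording):
        ch = derive_channels(healthy_recording.arm.accel, healthy_recording.arm.gyro)
        assert np.all(ch.A[:, 6] >= ch.A[:, 3:6].max(axis=1) - 1e-12)
        assert np.all(ch.W[:, 6] >= ch.W[:, 3:6].max(axis=1) - 1e-12)


class TestStatFeatures:
    def test_length_and_order(self, rng):
        ch = derive_channels(_sig(rng.normal(size=(50, 3))), _sig(rng.normal(size=(50, 3))))
        out = stat_features(ch)
        assert out.shape == (112,)
        # first 7 entries are the means of the acceleration channels
        np.testing.assert_allclose(out[:7], ch.A.mean(axis=0))

    def test_constant_channel_conventions(self):
        ch = derive_channels(_sig(np.full((20, 3), 2.0)), _sig(np.full((20, 3), 2.0)))
        out = stat_features(ch)
        per = {name: out[i * 14: (i + 1) * 14] for i, name in enumerate(
            ["mean", "std", "var", "max", "min", "range", "kurtosis", "skewness"])}
        np.testing.assert_allclose(per["mean"], per["max"])
        np.testing.assert_allclose(per["max"], per["min"])
        for zeroed in ["std", "var", "range", "kurtosis", "skewness"]:
            np.testing.assert_allclose(per[zeroed], 0.0, atol=1e-12)

    def test_hand_computed_example(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        xyz = np.column_stack([col, np.zeros(4), np.zeros(4)])
        ch = derive_channels(_sig(xyz), _sig(xyz))
        out = stat_features(ch)
        names = []
        for stat in ["mean", "std", "var", "max", "min", "range", "kurtosis", "skewness"]:
            for c in ACCEL_CHANNELS + tuple(f"g{c[1:]}" for c in ACCEL_CHANNELS):
                names.append(f"{stat}_{c}")
        vals = dict(zip(names, out))
        assert vals["mean_ax"] == pytest.approx(2.5)
        assert vals["range_ax"] == pytest.approx(3.0)
        assert vals["var_ax"] == pytest.approx(1.25)  # population variance


class TestNMCP:
    def test_constant_signal_never_crosses(self):
        assert nmcp(np.full(50, 3.3)) == 0

    def test_full_sine_period_crosses_twice(self):
        # small phase offset avoids samples landing exactly on the mean
        k = np.arange(128)
        x = np.sin(2 * np.pi * k / 128 + 0.1)
        s = x - x.mean()
        brute = sum(1 for i in range(127) if s[i] * s[i + 1] < 0)
        assert brute == 2
        assert nmcp(x) == 2

    def test_alternating_series(self):
        n = 21
        x = np.array([(-1.0) ** i for i in range(n)])
        assert nmcp(x) == n - 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force(self, seed):
        x = np.random.default_rng(seed).normal(size=40)
        s = x - x.mean()
        brute = sum(1 for i in range(39) if s[i] * s[i + 1] < 0)
        assert nmcp(x) == brute


class TestCountPeaks:
    def test_monotone_ramp_has_no_peaks(self):
        assert count_peaks(np.linspace(0, 1, 100)) == 0

    def test_flat_signal_returns_zero(self):
        assert count_peaks(np.zeros(100)) == 0

    def test_single_velocity_bell(self):
        t = np.linspace(0, 1, 128)
        assert count_peaks(minimum_jerk_velocity(t)) == 1

    def test_two_separated_gaussians(self):
        t = np.linspace(0, 1, 256)
        x = np.exp(-((t - 0.3) ** 2) / 0.002) + np.exp(-((t - 0.7) ** 2) / 0.002)
        assert count_peaks(x) == 2

    def test_low_prominence_bumps_ignored(self, rng):
        t = np.linspace(0, 1, 256)
        x = np.sin(np.pi * t) + 0.01 * rng.normal(size=256)
        assert count_peaks(x, prominence_frac=0.05) == 1


class TestSPARC:
    def test_always_negative(self, rng):
        for _ in range(10):
            assert sparc(_smooth_random_signal(rng), fs=128.0) < 0

    def test_fragmentation_lowers_sparc(self):
        fs = 128.0
        t = np.linspace(0, 1, 256)
        single = minimum_jerk_velocity(t)
        double = np.zeros_like(t)
        for onset in (0.0, 0.5):
            tau = np.clip((t - onset) / 0.5, 0, 1)
            double += minimum_jerk_velocity(tau)
        assert sparc(single, fs) > sparc(double, fs)

    def test_matches_dense_quadrature_oracle(self, rng):
        """Implementation at converged padding vs an independent dense quadrature.

        The oracle evaluates the spectrum with a chirp-z transform on a 10x
        finer frequency grid, finds its own cutoff, and integrates the arc
        length as a polyline — sharing no discretization with the
        implementation's rfft + gradient + trapezoid route.
        """
        from scipy.signal import czt

        def oracle(x, fs, padlevel=8, oversample=10):
            x = np.asarray(x, dtype=float)
            nfft = 2 ** (int(np.ceil(np.log2(x.size))) + padlevel)
            df = fs / nfft / oversample
            m = int(10.0 / df) + 1
            spectrum = np.abs(czt(x, m=m, w=np.exp(-2j * np.pi * df / fs), a=1.0))
            f = np.arange(m) * df
            vhat = spectrum / abs(x.sum())
            wc = f[np.nonzero(vhat >= 0.05)[0][-1]]
            sel = f <= wc
            seg = np.sqrt((np.diff(f[sel]) / wc) ** 2 + np.diff(vhat[sel]) ** 2)
            return -seg.sum()

        for _ in range(50):
            x = _random_speed_profile(rng)
            assert sparc(x, fs=128.0, padlevel=8) == pytest.approx(
                oracle(x, fs=128.0), abs=1e-3
            )

    def test_zero_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            sparc(np.zeros(64), fs=128.0)


class TestLDLJ:
    def test_amplitude_scale_invariance(self, rng):
        x = _smooth_random_signal(rng)
        assert ldlj(x, 128.0) == pytest.approx(ldlj(7.3 * x, 128.0), abs=1e-9)

    def test_smooth_beats_fragmented(self):
        t = np.linspace(0, 1, 256)
        bell = minimum_jerk_velocity(t)
        comp = np.zeros_like(t)
        for onset in (0.0, 0.5):
            tau = np.clip((t - onset) / 0.5, 0, 1)
            comp += minimum_jerk_velocity(tau)
        comp *= bell.max() / comp.max()  # equal peak
        assert ldlj(bell, 128.0) > ldlj(comp, 128.0)

    def test_time_rescale_invariance(self):
        # same continuous shape over T and 2T: duration^3 normalization cancels
        fs = 128.0
        t1 = np.linspace(0, 1, int(fs) + 1)
        t2 = np.linspace(0, 1, int(2 * fs) + 1)
        v1 = minimum_jerk_velocity(t1) + 0.2
        v2 = minimum_jerk_velocity(t2) + 0.2
        assert ldlj(v1, fs) == pytest.approx(ldlj(v2, fs), abs=1e-2)

    def test_zero_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            ldlj(np.zeros(64), 128.0)


class TestRangeAndPower:
    def test_constant_gyro_zero_range(self):
        assert rav(_sig(np.full((30, 3), 5.0))) == 0.0

    def test_rav_is_mean_of_axis_ranges(self):
        xyz = np.zeros((10, 3))
        xyz[0] = [0, 0, 0]
        xyz[5] = [1, 2, 3]
        assert rav(_sig(xyz)) == pytest.approx(2.0)

    def test_rav_matches_brute_force(self, rng):
        xyz = rng.normal(size=(100, 3))
        brute = np.mean([xyz[:, j].max() - xyz[:, j].min() for j in range(3)])
        assert rav(_sig(xyz)) == pytest.approx(brute)

    def test_power_index_hand_example(self):
        acc = np.zeros((10, 3)); acc[5] = [1, 1, 1]
        gyr = np.zeros((10, 3)); gyr[5] = [2, 3, 4]
        assert power_index(_sig(acc), _sig(gyr)) == pytest.approx(9.0)

    def test_power_index_zero_gyro(self, rng):
        acc = _sig(rng.normal(size=(50, 3)))
        assert power_index(acc, _sig(np.zeros((50, 3)))) == 0.0

    def test_power_index_matches_brute_force(self, rng):
        a, g = rng.normal(size=(80, 3)), rng.normal(size=(80, 3))
        brute = sum(
            (a[:, j].max() - a[:, j].min()) * (g[:, j].max() - g[:, j].min())
            for j in range(3)
        )
        assert power_index(_sig(a), _sig(g)) == pytest.approx(brute, abs=1e-9)


class TestFeatureVector:
    def test_kinematic_vector_length_and_symmetry(self, healthy_recording):
        s, e = healthy_recording.annotation.complete
        from fsid.core import extract_segment

        arm = extract_segment(healthy_recording.arm, (s, e))
        wrist = extract_segment(healthy_recording.wrist, (s, e))
        out = kinematic_features(arm, wrist, (e - s) / 128.0)
        assert out.shape == (13,)
        # feeding the arm twice makes every arm/wrist pair equal
        dup = kinematic_features(arm, arm, 1.0)
        np.testing.assert_allclose(dup[0::2][:6], dup[1::2][:6])

    def test_total_and_block_lengths(self, healthy_recording):
        fv = task_feature_vector(healthy_recording)
        schema = fv.schema
        assert len(fv.values) == 948
        stat = np.concatenate([schema.masks[("statistical", p)] for p in ("arm", "wrist")])
        kin = np.concatenate([schema.masks[("kinematic", p)] for p in ("arm", "wrist")])
        assert stat.size == 896 and kin.size == 52
        assert len(set(stat) | set(kin)) == 948  # masks partition the vector
        assert len(set(schema.names)) == 948

    def test_wrist_only_statistical_mask_width(self):
        schema = feature_schema()
        assert schema.masks[("statistical", "wrist")].size == 448
        assert schema.select("statistical", "wrist").size == 448
        assert schema.select("all", "both").size == 948

    def test_extraction_is_deterministic(self, healthy_recording):
        a = task_feature_vector(healthy_recording).values
        b = task_feature_vector(healthy_recording).values
        np.testing.assert_array_equal(a, b)

    def test_fs_task_lasts_longer_than_healthy(self, healthy_recording, fs_recording):
        h = task_feature_vector(healthy_recording)
        f = task_feature_vector(fs_recording)
        dur_idx = h.schema.names.index("complete.kin.duration")
        assert f.values[dur_idx] > h.values[dur_idx]

    def test_cohort_table_is_finite(self, tiny_features):
        vals = tiny_features.drop(columns=["subject_id", "group", "task"]).to_numpy()
        assert vals.shape == (40, 948)
        assert np.all(np.isfinite(vals))
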