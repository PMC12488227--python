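"""Velocity/acceleration, peak extraction, ROM metrics, screening, and the
gyroscope-integrated fallback."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import lumbokin as lk
from lumbokin import metrics as mx, simulate as sim
from lumbokin.errors import NoRepsDetected, TooShort
from lumbokin.kinematics import EulerSeries
from lumbokin.types import (SegmentPair, Sensor, SensorStream, TestId,
                            TrialRecording, Pace)


def _euler(pair=SegmentPair.TRUNK, alpha=None, gamma=None, beta=None,
           n=400, fs=62.5):
    z = np.zeros(n)
    series = {"alpha": z.copy() if alpha is None else np.asarray(alpha, float),
              "gamma": z.copy() if gamma is None else np.asarray(gamma, float),
              "beta": z.copy() if beta is None else np.asarray(beta, float)}
    return EulerSeries(pair, series["alpha"], series["gamma"],
                       series["beta"], fs, np.zeros(n, bool))


def _const_gyro_trial(gyro_moving, gyro_ref=(0.0, 0, 0), n=200, fs=62.5):
    t = np.arange(n) / fs
    quat = np.zeros((n, 4))
    quat[:, 0] = 1.0
    accel = np.tile([1.0, 0, 0], (n, 1))
    streams = {}
    for sensor, g in ((SegmentPair.LUMBAR.reference, gyro_ref),
                      (SegmentPair.LUMBAR.moving, gyro_moving)):
        streams[sensor] = SensorStream(sensor, t, quat.copy(),
                                       np.tile(g, (n, 1)), accel.copy())
    return TrialRecording("p", TestId.FE_SELF, Pace.SELF, streams)


class TestVelocity:
    def test_constant_gyro_passes_through(self):
        trial = _const_gyro_trial((0.0, 0, 50.0))
        vel = mx.anatomical_angular_velocity(trial,
                                             lk.AlignmentResult.identity())
        v = vel[SegmentPair.LUMBAR]
        np.testing.assert_allclose(v[50:-50], [[0.0, 0, 50.0]] * 100,
                                   atol=1e-6)

    def test_scripted_sinusoid_peak_velocity(self):
        script = sim.sinusoid_script({"lumbar": 40.0}, 0.5, 3)
        rec, _ = sim.simulate_trial(script, sim.RigConfig.ideal(0))
        kinser = mx.compute_kinematics(rec, lk.AlignmentResult.identity())
        v = kinser.velocity[SegmentPair.LUMBAR][:, 1]
        n = len(v)
        peak = np.abs(v[n // 6: -n // 6]).max()
        assert peak == pytest.approx(2 * np.pi * 0.5 * 40.0, rel=0.02)

    def test_filter_contracts_white_noise(self, rng):
        trial = _const_gyro_trial((0.0, 0, 0), n=2000)
        s = trial.streams[SegmentPair.LUMBAR.moving]
        s.gyro = rng.normal(0, 5.0, s.gyro.shape)
        vel = mx.anatomical_angular_velocity(trial,
                                             lk.AlignmentResult.identity())
        assert np.std(vel[SegmentPair.LUMBAR]) < np.std(s.gyro)


class TestDifferentiate:
    def test_constant_velocity_zero_acceleration(self):
        a = mx.differentiate_series(np.full(100, 7.0), 62.5)
        assert np.abs(a).max() < 1e-9

    def test_linear_ramp_exact_slope(self):
        fs = 62.5
        v = 3.0 * np.arange(100) / fs
        a = mx.differentiate_series(v, fs)
        np.testing.assert_allclose(a, 3.0, atol=1e-9)

    def test_sinusoid_peak_acceleration(self):
        fs, f, V = 62.5, 0.5, 80.0
        t = np.arange(1000) / fs
        a = mx.differentiate_series(V * np.sin(2 * np.pi * f * t), fs)
        assert np.abs(a[100:-100]).max() == pytest.approx(
            2 * np.pi * f * V, rel=0.02)

    def test_too_short(self):
        with pytest.raises(TooShort):
            mx.differentiate_series(np.array([1.0, 2.0]), 62.5)


class TestRepPeaks:
    def test_three_clean_cycles(self):
        fs = 62.5
        t = np.arange(int(3 * 2 * fs)) / fs
        x = 30 * np.sin(2 * np.pi * 0.5 * t)
        peaks = mx.extract_rep_peaks(x, expected_reps=3)
        highs = [i for i, v in peaks if v > 0]
        lows = [i for i, v in peaks if v < 0]
        assert len(highs) == 3 and len(lows) == 3
        for k, i in enumerate(highs):
            assert abs(i - (0.5 + 2 * k) * fs) <= 1

    def test_simulated_sit_to_stand_five_positive_peaks(self, sims, align0,
                                                        angles_of):
        e = angles_of(TestId.FSTS)[SegmentPair.HIP]
        peaks = mx.extract_rep_peaks(e.beta, 5, polarity="positive")
        assert len(peaks) == 5

    def test_flat_series_raises(self):
        with pytest.raises(NoRepsDetected):
            mx.extract_rep_peaks(np.zeros(100), 3)


class TestTrimmedMean:
    def test_plain_mean_at_zero_trim(self):
        assert mx.trimmed_mean_abs([10, -10, 10, -10], 0.0) == 10.0

    def test_hand_example_drops_extremes(self):
        assert mx.trimmed_mean_abs([8, 9, 10, 11, 50], 0.2) == 10.0

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50),
           st.floats(0, 0.45))
    def test_matches_sort_and_slice_oracle(self, values, trim):
        v = np.sort(np.abs(np.asarray(values)))
        k = int(np.floor(trim * len(v)))
        if len(v) - 2 * k <= 0:
            k = 0
        expect = v[k: len(v) - k].mean()
        assert mx.trimmed_mean_abs(values, trim) == pytest.approx(
            expect, rel=1e-12, abs=1e-12)

    def test_agrees_with_scipy_trim_mean(self, rng):
        for _ in range(50):
            v = rng.normal(0, 10, rng.integers(6, 40))
            assert mx.trimmed_mean_abs(v, 0.2) == pytest.approx(
                stats.trim_mean(np.abs(v), 0.2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mx.trimmed_mean_abs([])


class TestRomSelfPaced:
    def test_signed_extremes_and_total(self):
        t = np.linspace(0, 2 * np.pi, 400)
        gamma = np.where(t < np.pi, 25 * np.sin(t), -30 * np.abs(np.sin(t)))
        met = mx.rom_self_paced(_euler(gamma=gamma), TestId.LB_SELF)
        # lateral bend, spinal pair: left reported positive
        assert met.rom_dir1 == pytest.approx(25.0, abs=0.05)
        assert met.rom_dir2 == pytest.approx(-30.0, abs=0.05)
        assert met.rom_total == pytest.approx(55.0, abs=0.1)

    def test_axial_rotation_table_signs(self, angles_of, sims):
        _, gt = sims[TestId.AR_SELF]
        e = angles_of(TestId.AR_SELF)[SegmentPair.TRUNK]
        met = mx.rom_self_paced(e, TestId.AR_SELF)
        # spinal axial rotation: left negative, right positive
        assert met.directions == ("left", "right")
        assert met.rom_dir1 < 0 < met.rom_dir2
        assert met.rom_total == pytest.approx(
            gt.rom[SegmentPair.TRUNK]["total"], abs=1.0)

    def test_hip_flexion_sign_flipped_vs_spinal(self, angles_of, sims):
        angles = angles_of(TestId.FE_SELF)
        lum = mx.rom_self_paced(angles[SegmentPair.LUMBAR], TestId.FE_SELF)
        hip = mx.rom_self_paced(angles[SegmentPair.HIP], TestId.FE_SELF)
        assert lum.rom_dir1 < 0  # spinal flexion negative
        assert hip.rom_dir1 > 0  # hip flexion positive
        assert hip.rom_dir2 < 0  # hip extension negative

    def test_total_is_sum_of_magnitudes(self, angles_of):
        for test in (TestId.AR_SELF, TestId.LB_SELF, TestId.FE_SELF):
            for e in angles_of(test).values():
                met = mx.rom_self_paced(e, test)
                assert met.rom_total == pytest.approx(
                    abs(met.rom_dir1) + abs(met.rom_dir2), abs=1e-9)


class TestRomFunctional:
    def test_identical_lifts(self):
        fs = 62.5
        t = np.arange(int(4 * 4 * fs)) / fs
        beta = 80 * 0.5 * (1 - np.cos(2 * np.pi * t / 4.0))
        met = mx.rom_functional(_euler(beta=beta, n=len(t)), TestId.PLS, 4)
        assert met.rom_mean == pytest.approx(80.0, abs=0.1)
        assert met.n_reps == 4

    def test_varying_rep_excursions_averaged(self):
        script = sim.make_motion_script(
            TestId.PLS, amplitudes={"hip": (70.0, 75.0, 80.0, 85.0)})
        rec, _ = sim.simulate_trial(script, sim.RigConfig.ideal(0))
        angles, _ = lk.compute_segment_angles(rec,
                                              lk.AlignmentResult.identity())
        met = mx.rom_functional(angles[SegmentPair.HIP], TestId.PLS)
        assert met.rom_mean == pytest.approx(77.5, abs=1.0)
        assert met.n_reps == 4

    def test_single_rep_is_its_excursion(self):
        fs = 62.5
        t = np.arange(int(4 * fs)) / fs
        beta = 60 * 0.5 * (1 - np.cos(2 * np.pi * t / 4.0))
        met = mx.rom_functional(_euler(beta=beta, n=len(t)), TestId.PLS, 1)
        assert met.n_reps == 1
        assert met.rom_mean == pytest.approx(60.0, abs=0.1)


class TestIntegratedRom:
    def test_constant_rate_analytic_integral(self):
        trial = _const_gyro_trial((0.0, 10.0, 0.0),
                                  n=int(3 * 62.5) + 1)  # 3 s at 10 deg/s
        rom = mx.integrated_rom(trial, lk.AlignmentResult.identity(),
                                SegmentPair.LUMBAR, "beta")
        assert rom == pytest.approx(30.0, abs=0.2)

    def test_clean_trial_agrees_with_orientation_rom(self, sims, align0):
        rec, gt = sims[TestId.FE_SELF]
        angles, _ = lk.compute_segment_angles(rec, align0)
        for pair in SegmentPair:
            quat_rom = float(np.ptp(angles[pair].beta))
            int_rom = mx.integrated_rom(rec, align0, pair, "beta")
            assert abs(quat_rom - int_rom) < 0.5, pair

    def test_drift_corrupted_trial_resolved_by_integration(self, sims,
                                                           align0):
        rec, gt = sims[TestId.FE_SELF]
        truth = gt.rom[SegmentPair.LUMBAR]["total"]
        bad = sim.corrupt_stream(rec, "fusion_drift", 1.0, seed=3,
                                 sensors=[Sensor.L1],
                                 axis=np.array([0.0, 1.0, 0.0]))
        angles, _ = lk.compute_segment_angles(bad, align0)
        quat_rom = float(np.ptp(angles[SegmentPair.LUMBAR].beta))
        int_rom = mx.integrated_rom(bad, align0, SegmentPair.LUMBAR, "beta")
        assert abs(int_rom - truth) < 1.0
        assert abs(quat_rom - truth) > 3.0  # fusion channel is off by drift


class TestScreening:
    def test_clean_symmetric_trial_unflagged(self, angles_of):
        e = angles_of(TestId.AR_SELF)[SegmentPair.TRUNK]
        met = mx.rom_self_paced(e, TestId.AR_SELF)
        assert mx.flag_unexpected_movement(met, e, TestId.AR_SELF) == []

    def test_excursion_beyond_physiologic_bound_flagged(self):
        t = np.linspace(0, 2 * np.pi, 500)
        alpha = 90 * np.sin(t)  # 180 deg total axial rotation
        e = _euler(alpha=alpha, n=500)
        met = mx.rom_self_paced(e, TestId.AR_SELF)
        flags = mx.flag_unexpected_movement(met, e, TestId.AR_SELF)
        assert "out_of_range" in flags

    def test_asymmetric_sides_flagged(self):
        t = np.linspace(0, 2 * np.pi, 500)
        alpha = np.where(t < np.pi, 40 * np.sin(t), -8 * np.abs(np.sin(t)))
        e = _euler(alpha=alpha, n=500)
        met = mx.rom_self_paced(e, TestId.AR_SELF)
        assert "asymmetry" in mx.flag_unexpected_movement(
            met, e, TestId.AR_SELF)

    def test_wrong_first_direction_flagged(self):
        t = np.linspace(0, 2 * np.pi, 500)
        alpha = np.where(t < np.pi, -40 * np.sin(t), 40 * np.abs(np.sin(t)))
        e = _euler(alpha=alpha, n=500)
        met = mx.rom_self_paced(e, TestId.AR_SELF)
        assert "wrong_direction" in mx.flag_unexpected_movement(
            met, e, TestId.AR_SELF)

    def test_flagged_trial_rerouted_through_integration(self, sims, align0):
        rec, gt = sims[TestId.FE_SELF]
        # drift one sensor against the cued direction: the screen must
        # catch it (shared drift would cancel in the relative rotations)
        bad = sim.corrupt_stream(rec, "fusion_drift", 3.0, seed=3,
                                 sensors=[Sensor.L1],
                                 axis=np.array([0.0, -1.0, 0.0]))
        angles, _ = lk.compute_segment_angles(bad, align0)
        mets = {m.pair: m for m in mx.analyze_trial(bad, align0, angles)}
        rerouted = [m for m in mets.values() if m.method == "integrated"]
        for m in rerouted:
            assert m.rom_total == pytest.approx(
                gt.rom[m.pair]["total"], abs=1.5)
        assert rerouted, "expected at least one pair to fail screening"
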