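"""Rotation conversion, Euler decomposition, unwrapping, filtering, and the
full angle chain."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import lumbokin as lk
from lumbokin import kinematics as kin
from lumbokin.errors import StreamError, TooShort
from lumbokin.types import SegmentPair, Sensor, TestId


class TestQuatToRotation:
    def test_identity(self):
        np.testing.assert_allclose(
            lk.quat_to_rotation(np.array([1.0, 0, 0, 0])), np.eye(3))

    def test_ninety_about_z(self):
        q = np.array([np.sqrt(2) / 2, 0, 0, np.sqrt(2) / 2])
        expect = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
        np.testing.assert_allclose(lk.quat_to_rotation(q), expect,
                                   atol=1e-12)

    def test_matches_sandwich_product(self, rng):
        # R v must equal the Hamilton sandwich q v q* on basis vectors
        q = rng.normal(size=(1000, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        R = lk.quat_to_rotation(q)

        def hamilton(a, b):
            w1, x1, y1, z1 = a.T
            w2, x2, y2, z2 = b.T
            return np.stack([
                w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
                w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
                w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
                w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2], axis=1)

        conj = q * np.array([1.0, -1, -1, -1])
        for k in range(3):
            v = np.zeros((len(q), 4))
            v[:, 1 + k] = 1.0
            sandwich = hamilton(hamilton(q, v), conj)[:, 1:]
            np.testing.assert_allclose(R[:, :, k], sandwich, atol=1e-12)

    def test_zero_quaternion_rejected(self):
        with pytest.raises(ValueError):
            lk.quat_to_rotation(np.zeros(4))


class TestDecomposeXZY:
    def test_identity(self):
        a, g, b, flag = lk.decompose_xzy(np.eye(3))
        assert (a, g, b) == (0.0, 0.0, 0.0) and not flag

    def test_compose_decompose_round_trip(self):
        R = lk.compose_xzy(25.0, -10.0, 40.0)
        a, g, b, flag = lk.decompose_xzy(R)
        assert not flag
        np.testing.assert_allclose([a, g, b], [25.0, -10.0, 40.0],
                                   atol=1e-9)

    def test_round_trip_reconstruction_vectorized(self, rng):
        n = 10_000
        alpha = rng.uniform(-179, 179, n)
        gamma = rng.uniform(-85, 85, n)
        beta = rng.uniform(-179, 179, n)
        R = lk.compose_xzy(alpha, gamma, beta)
        a, g, b, flags = lk.decompose_xzy(R)
        R2 = lk.compose_xzy(a, g, b)
        assert not flags.any()
        assert np.abs(R2 - R).max() < 1e-9

    def test_agrees_with_scipy_euler(self, rng):
        # independent oracle: scipy's intrinsic X-Z-Y Euler angles
        q = rng.normal(size=(200, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        R = lk.quat_to_rotation(q)
        a, g, b, flags = lk.decompose_xzy(R)
        ref = Rotation.from_matrix(R).as_euler("XZY", degrees=True)
        keep = ~flags
        np.testing.assert_allclose(
            np.column_stack([a, g, b])[keep], ref[keep], atol=1e-8)

    def test_gimbal_flagged_at_ninety(self):
        R = lk.compose_xzy(30.0, 90.0, 0.0)
        _, g, b, flag = lk.decompose_xzy(R)
        assert flag and b == 0.0 and g == pytest.approx(90.0)

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValueError):
            lk.decompose_xzy(np.eye(3) * 1.01)


class TestNeutralReference:
    def test_constant_start_removed(self):
        R0 = lk.compose_xzy(5.0, 3.0, -7.0)
        later = lk.compose_xzy(10.0, 0.0, 20.0)
        series = kin.RotationSeries(
            np.concatenate([np.repeat(R0[None], 5, axis=0), later[None]]),
            62.5)
        out = lk.kinematics.neutral_reference(series)
        np.testing.assert_allclose(out.R[0], np.eye(3), atol=1e-12)
        np.testing.assert_allclose(out.R[5], R0.T @ later, atol=1e-12)

    def test_symmetric_spread_averages_to_identity(self):
        # Rz of (-2,-1,0,1,2) deg: chordal mean is Rz(0)
        R = lk.compose_xzy(np.zeros(5), np.array([-2.0, -1, 0, 1, 2]),
                           np.zeros(5))
        out = lk.kinematics.neutral_reference(kin.RotationSeries(R, 62.5))
        # the neutral equals Rz(0): the middle sample maps to identity and
        # the outer samples stay symmetric about it
        np.testing.assert_allclose(out.R[2], np.eye(3), atol=1e-6)
        np.testing.assert_allclose(out.R[0], out.R[4].T, atol=1e-9)

    def test_too_short(self):
        series = kin.RotationSeries(np.repeat(np.eye(3)[None], 4, axis=0),
                                    62.5)
        with pytest.raises(TooShort):
            lk.kinematics.neutral_reference(series)


class TestUnwrap:
    def test_continuous_series_unchanged(self):
        x = np.linspace(-170, 170, 100)
        np.testing.assert_array_equal(lk.unwrap_series(x), x)

    def test_single_wrap(self):
        np.testing.assert_allclose(lk.unwrap_series(np.array([179.0, -179.0])),
                                   [179.0, 181.0])

    @given(st.lists(st.floats(-170, 170), min_size=2, max_size=60))
    def test_matches_minimal_difference_oracle(self, steps):
        # brute force: accumulate the representative difference in (-180,180]
        walk = np.cumsum(np.asarray(steps))
        wrapped = ((walk + 180.0) % 360.0) - 180.0
        out = lk.unwrap_series(wrapped)
        expect = [wrapped[0]]
        for d in np.diff(wrapped):
            d = ((d + 180.0) % 360.0) - 180.0
            expect.append(expect[-1] + d)
        np.testing.assert_allclose(out, expect, atol=1e-9)


class TestFilter:
    def test_constant_unchanged(self):
        x = np.full(200, 3.7)
        assert np.abs(lk.lowpass_zero_phase(x) - 3.7).max() < 1e-9

    def test_passband_amplitude_and_zero_lag(self):
        fs, f = 62.5, 1.0
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * f * t)
        y = lk.lowpass_zero_phase(x)
        assert np.abs(y[200:-200]).max() >= 0.99
        lags = np.arange(-20, 21)
        cc = [np.dot(x[200:-200], np.roll(y, k)[200:-200]) for k in lags]
        assert lags[int(np.argmax(cc))] == 0

    def test_stopband_attenuation_matches_squared_butterworth(self):
        fs, f = 62.5, 15.0
        t = np.arange(2000) / fs
        y = lk.lowpass_zero_phase(np.sin(2 * np.pi * f * t))
        amp = np.abs(y[500:-500]).max()
        # analog 3rd-order bound applied twice: |H|^2 = 1/(1 + (15/5)^6);
        # the bilinear-transform digital filter attenuates at least as much
        # this close to Nyquist
        assert 1e-6 < amp < 1.0 / (1.0 + 3.0 ** 6)
        assert amp < 0.01

    @given(st.floats(-500, 500))
    def test_commutes_with_constant_offset(self, c):
        t = np.arange(300) / 62.5
        x = 10 * np.sin(2 * np.pi * 0.8 * t)
        lhs = lk.lowpass_zero_phase(x + c)
        rhs = lk.lowpass_zero_phase(x) + c
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_too_short(self):
        with pytest.raises(TooShort):
            lk.lowpass_zero_phase(np.zeros(5))


class TestRelativeRotation:
    def test_identity_throughout(self):
        R = np.repeat(np.eye(3)[None], 10, axis=0)
        out = kin.relative_rotation_series(
            kin.RotationSeries(R, 62.5), kin.RotationSeries(R, 62.5),
            lk.AlignmentResult.identity(), SegmentPair.LUMBAR)
        assert np.abs(out.R - np.eye(3)).max() < 1e-12

    def test_pure_distal_rotation(self):
        prox = kin.RotationSeries(np.repeat(np.eye(3)[None], 4, axis=0), 62.5)
        dist = kin.RotationSeries(
            np.repeat(lk.compose_xzy(0, 30.0, 0)[None], 4, axis=0), 62.5)
        out = kin.relative_rotation_series(prox, dist,
                                           lk.AlignmentResult.identity(),
                                           SegmentPair.LUMBAR)
        ang = np.rad2deg(np.arccos((np.trace(out.R[0]) - 1) / 2))
        assert ang == pytest.approx(30.0, abs=1e-9)

    def test_length_mismatch(self):
        a = kin.RotationSeries(np.repeat(np.eye(3)[None], 4, axis=0), 62.5)
        b = kin.RotationSeries(np.repeat(np.eye(3)[None], 5, axis=0), 62.5)
        with pytest.raises(StreamError):
            kin.relative_rotation_series(a, b, lk.AlignmentResult.identity(),
                                         SegmentPair.LUMBAR)


class TestSegmentAngles:
    def test_static_trial_angles_below_tenth_degree(self):
        from lumbokin import simulate as sim
        rec, _ = sim.simulate_trial(sim.quiet_script(3.0),
                                    sim.RigConfig.ideal(0))
        angles, _ = lk.compute_segment_angles(rec,
                                              lk.AlignmentResult.identity())
        for e in angles.values():
            for axis in ("alpha", "gamma", "beta"):
                assert np.abs(e.axis(axis)).max() < 0.1

    def test_axial_rotation_extrema_recovered(self, sims, align0):
        rec, gt = sims[TestId.AR_SELF]
        angles, _ = lk.compute_segment_angles(rec, align0)
        a = angles[SegmentPair.TRUNK].alpha
        assert a.max() == pytest.approx(32.0, abs=0.5)
        assert a.min() == pytest.approx(-32.0, abs=0.5)

    def test_missing_hip_omits_only_hip_pair(self, sims, align0):
        rec, _ = sims[TestId.AR_SELF]
        partial = lk.TrialRecording(
            rec.participant_id, rec.test_id, rec.pace,
            {s: st for s, st in rec.streams.items() if s is not Sensor.HIP},
            rec.sex, rec.age, rec.fs)
        angles, omitted = lk.compute_segment_angles(partial, align0)
        assert SegmentPair.HIP in omitted and "HIP" in omitted[SegmentPair.HIP]
        assert set(angles) == {SegmentPair.TRUNK, SegmentPair.THORACIC,
                               SegmentPair.LUMBAR}

    def test_end_to_end_recovery_all_tests(self, sims, align0):
        # zero noise, random <= 15 deg mounts: every pair/axis within 0.5 deg
        for test_id, (rec, gt) in sims.items():
            angles, _ = lk.compute_segment_angles(rec, align0)
            for pair, e in angles.items():
                for axis in ("alpha", "gamma", "beta"):
                    err = np.abs(e.axis(axis) - gt.angles[pair][axis]).max()
                    assert err < 0.5, (test_id, pair, axis, err)
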