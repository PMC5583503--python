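import numpy as np
import pytest
from hypothesis import given, strategies as st

from repform import (
    SIGNAL_NAMES,
    build_signal_set,
    estimate_orientation,
    lowpass_filter,
    quaternion_to_euler,
    vector_magnitude,
)
from repform.preprocess import euler_to_quaternion, orientation_from_acc_mag
from repform.synth import EARTH_FIELD, _quat_to_matrix

FS = 51.2


def analytic_zero_phase_gain(f, fc=20.0, order=8):
    # forward-backward filtering squares the Butterworth magnitude response
    return 1.0 / (1.0 + (f / fc) ** (2 * order))


class TestLowpass:
    def test_dc_passthrough(self):
        out = lowpass_filter(np.full(500, 5.0), FS)
        np.testing.assert_allclose(out, 5.0, rtol=1e-9)

    @pytest.mark.parametrize("freq,tol", [(2.0, 0.01), (24.0, None)])
    def test_sinusoid_attenuation_matches_analytic_magnitude(self, freq, tol):
        t = np.arange(int(20 * FS)) / FS
        out = lowpass_filter(np.sin(2 * np.pi * freq * t), FS)
        mid = slice(len(t) // 4, 3 * len(t) // 4)  # avoid edge transients
        measured = np.max(np.abs(out[mid]))
        expected = analytic_zero_phase_gain(freq)
        if tol is not None:
            assert measured == pytest.approx(expected, rel=tol)
        else:
            assert measured <= 0.06  # (24/20)^16 stop-band term

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(500), FS, fc=30.0)  # >= Nyquist
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(10), FS)  # too short for order 8

    @given(
        a=st.floats(-5, 5, allow_nan=False),
        b=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_linearity(self, a, b, seed):
        rng = np.random.default_rng(seed)
        s1, s2 = rng.normal(size=(2, 300))
        lhs = lowpass_filter(a * s1 + b * s2, FS)
        rhs = a * lowpass_filter(s1, FS) + b * lowpass_filter(s2, FS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9 * max(1.0, abs(a) + abs(b)))


def static_marg(pitch, roll=0.0, n=300):
    q = euler_to_quaternion(pitch, roll, 0.0)
    rot = _quat_to_matrix(q[None, :])[0]
    acc = np.tile(rot[2, :], (n, 1))
    mag = np.tile(EARTH_FIELD @ rot, (n, 1))
    return acc, np.zeros((n, 3)), mag


class TestOrientation:
    def test_gravity_aligned_identity(self):
        acc, gyro, mag = static_marg(0.0)
        pitch, roll, _ = quaternion_to_euler(estimate_orientation(acc, gyro, mag, FS))
        assert abs(pitch[-1]) < 1e-3 and abs(roll[-1]) < 1e-3

    @pytest.mark.parametrize("true_pitch", [0.5, -0.3])
    def test_static_tilt_recovered(self, true_pitch):
        acc, gyro, mag = static_marg(true_pitch)
        pitch, _, _ = quaternion_to_euler(estimate_orientation(acc, gyro, mag, FS))
        assert pitch[-1] == pytest.approx(true_pitch, abs=5e-3)

    def test_static_tilt_converges_from_identity_init(self):
        acc, gyro, mag = static_marg(0.5, n=600)
        q = estimate_orientation(acc, gyro, mag, FS, q0=np.array([1.0, 0, 0, 0]))
        pitch, _, _ = quaternion_to_euler(q)
        assert pitch[-1] == pytest.approx(0.5, abs=5e-3)

    def test_constant_rate_integration(self):
        omega = 0.1  # rad/s about the pitch axis
        n = int(10 * FS)
        theta = omega * np.arange(n) / FS
        qs = euler_to_quaternion(theta, np.zeros(n), np.zeros(n))
        rot = _quat_to_matrix(qs)
        acc = rot[:, 2, :]
        mag = np.einsum("nij,i->nj", rot, EARTH_FIELD)
        gyro = np.column_stack([np.zeros(n), np.full(n, omega), np.zeros(n)])
        pitch, _, _ = quaternion_to_euler(estimate_orientation(acc, gyro, mag, FS))
        np.testing.assert_allclose(pitch, theta, atol=0.02)

    def test_unit_norm_invariant(self, clean_signals):
        q = np.column_stack([clean_signals[c] for c in ("quat_w", "quat_x", "quat_y", "quat_z")])
        np.testing.assert_allclose(np.linalg.norm(q, axis=1), 1.0, atol=1e-9)

    def test_zero_norm_accelerometer_sample_propagates_gyro_only(self):
        acc, gyro, mag = static_marg(0.2)
        acc[50] = 0.0  # dropout sample: correction skipped, no crash
        pitch, _, _ = quaternion_to_euler(estimate_orientation(acc, gyro, mag, FS))
        assert pitch[-1] == pytest.approx(0.2, abs=5e-3)

    def test_orientation_recovery_on_zero_noise_session(self, clean_session, clean_signals):
        cfg, stream, truth = clean_session
        from repform.synth import simulate_repetition

        # reconstruct the ground-truth pitch trajectory
        pitch_true = np.zeros(len(stream))
        for k, (start, _, _) in enumerate(truth.boundaries):
            rep = simulate_repetition(cfg, k)
            pitch_true[start : start + len(rep["pitch"])] = rep["pitch"]
        rms = np.sqrt(np.mean((clean_signals["pitch"] - pitch_true) ** 2))
        assert rms < 0.05


class TestEulerConversion:
    def test_identity(self):
        pitch, roll, yaw = quaternion_to_euler(np.array([[1.0, 0, 0, 0]]))
        assert pitch[0] == roll[0] == yaw[0] == 0.0

    def test_quarter_turn_about_y_is_gimbal_pitch(self):
        s = np.sqrt(2) / 2
        pitch, _, _ = quaternion_to_euler(np.array([[s, 0.0, s, 0.0]]))
        assert pitch[0] == pytest.approx(np.pi / 2, abs=1e-9)

    def test_round_trip_random_orientations(self, rng):
        n = 1000
        pitch = rng.uniform(-np.pi / 2 + 0.05, np.pi / 2 - 0.05, n)
        roll = rng.uniform(-np.pi + 0.01, np.pi - 0.01, n)
        yaw = rng.uniform(-np.pi + 0.01, np.pi - 0.01, n)
        q = euler_to_quaternion(pitch, roll, yaw)
        p2, r2, y2 = quaternion_to_euler(q)
        for a, b in [(pitch, p2), (roll, r2), (yaw, y2)]:
            assert np.max(np.abs(a - b)) < 1e-9

    def test_algebraic_init_matches_truth(self):
        q_true = euler_to_quaternion(0.4, -0.2, 0.3)
        rot = _quat_to_matrix(q_true[None, :])[0]
        q0 = orientation_from_acc_mag(rot[2, :], EARTH_FIELD @ rot)
        assert np.abs(q0 - q_true).max() < 1e-9 or np.abs(q0 + q_true).max() < 1e-9


class TestVectorMagnitude:
    def test_pythagorean_triple(self):
        assert vector_magnitude([3.0], [4.0], [0.0])[0] == 5.0

    def test_matches_norm_oracle(self, rng):
        x, y, z = rng.normal(size=(3, 100))
        expected = [np.sqrt(a * a + b * b + c * c) for a, b, c in zip(x, y, z)]
        np.testing.assert_allclose(vector_magnitude(x, y, z), expected, rtol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            vector_magnitude([1, 2], [1], [1, 2])


class TestBuildSignalSet:
    def test_exact_channel_names_and_lengths(self, clean_session, clean_signals):
        _, stream, _ = clean_session
        assert tuple(clean_signals.channels.keys()) == SIGNAL_NAMES
        assert all(len(clean_signals[c]) == len(stream) for c in SIGNAL_NAMES)

    def test_stationary_segment_values(self):
        from repform import SynthConfig, generate_session
        from conftest import ZERO_NOISE

        cfg = SynthConfig(n_reps=1, pitch_amplitude=0.0, rest_gap=2.0, **ZERO_NOISE)
        stream, _ = generate_session(cfg)
        signals = build_signal_set(stream)
        mid = len(signals) // 2
        assert abs(signals["pitch"][mid]) < 1e-3
        assert abs(signals["roll"][mid]) < 1e-3
        assert signals["acc_mag"][mid] == pytest.approx(1.0, abs=1e-6)
        assert signals["gyro_mag"][mid] == pytest.approx(0.0, abs=1e-3)
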