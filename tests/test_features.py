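import numpy as np
import pytest

from repform import (
    DESCRIPTOR_NAMES,
    FEATURE_NAMES,
    SIGNAL_NAMES,
    build_feature_matrix,
    compute_feature_vector,
)
from repform.features import (
    descriptor,
    higuchi_fd,
    level_crossing_rate,
    wavelet_variances,
)

from _oracles import ORACLES


class TestDescriptorArithmetic:
    def test_hand_arithmetic(self):
        x = np.array([1.0, 2.0, 3.0])
        assert descriptor("mean", x) == 2.0
        assert descriptor("range", x) == 2.0
        assert descriptor("energy", x) == 14.0
        assert descriptor("median", x) == 2.0

    def test_rms_of_constant_is_abs(self):
        assert descriptor("rms", np.full(10, -3.0)) == pytest.approx(3.0)

    def test_constant_conventions(self):
        c = np.full(64, 2.5)
        assert descriptor("kurtosis", c) == 0.0
        assert descriptor("skewness", c) == 0.0
        assert level_crossing_rate(c) == 0.0

    def test_too_short_epoch(self):
        with pytest.raises(ValueError):
            descriptor("mean", np.array([1.0]))

    def test_unknown_descriptor(self):
        with pytest.raises(ValueError):
            descriptor("entropy", np.zeros(10))


class TestHiguchi:
    def test_straight_line_dimension_one(self):
        assert 1.0 <= higuchi_fd(np.linspace(0, 5, 1024)) + 1e-9 <= 1.05

    def test_white_noise_dimension_two(self, rng):
        assert 1.9 <= higuchi_fd(rng.standard_normal(1024)) <= 2.05


class TestWaveletVariances:
    def test_zero_signal(self):
        assert wavelet_variances(np.zeros(256)) == (0.0, 0.0)

    def test_constant_has_no_detail_energy(self):
        approx_var, detail_var = wavelet_variances(np.full(256, 3.7))
        assert detail_var < 1e-20

    def test_short_epoch_depth_reduced_not_padded(self):
        # 77 samples supports only 3 db5 levels; must not error
        approx_var, detail_var = wavelet_variances(np.sin(np.arange(77) / 5))
        assert np.isfinite(approx_var) and np.isfinite(detail_var)


class TestOracleEquivalence:
    @pytest.mark.parametrize("desc", DESCRIPTOR_NAMES)
    def test_descriptor_matches_literal_definition(self, desc, rng):
        for _ in range(20):
            n = int(rng.integers(32, 400))
            x = rng.normal(loc=rng.uniform(-2, 2), scale=rng.uniform(0.1, 5), size=n)
            got = descriptor(desc, x)
            want = ORACLES[desc](list(x))
            assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


class TestFeatureVector:
    def test_exactly_306_named_features(self, clean_signals):
        from repform import segment_repetitions

        rep = segment_repetitions(clean_signals)[0]
        fv = compute_feature_vector(rep)
        assert len(fv) == 306
        assert fv.names == FEATURE_NAMES
        assert np.isfinite(fv.values).all()

    def test_name_order_channels_by_descriptors(self):
        assert FEATURE_NAMES[0] == "acc_x__mean"
        assert FEATURE_NAMES[17] == "acc_y__mean"
        assert FEATURE_NAMES[-1] == "gyro_mag__wavelet_detail_var"
        assert len(FEATURE_NAMES) == len(SIGNAL_NAMES) * len(DESCRIPTOR_NAMES) == 306

    def test_determinism(self, clean_signals):
        from repform import segment_repetitions

        rep = segment_repetitions(clean_signals)[0]
        np.testing.assert_array_equal(
            compute_feature_vector(rep).values, compute_feature_vector(rep).values
        )

    def test_channel_scaling_homogeneity(self, clean_signals):
        from repform import segment_repetitions

        rep = segment_repetitions(clean_signals)[0]
        base = compute_feature_vector(rep)
        scaled_signals = rep.signals.slice(0, len(rep.signals))
        scaled_signals.channels["mag_x"] = 2.0 * scaled_signals.channels["mag_x"]
        import dataclasses

        scaled_rep = dataclasses.replace(rep, signals=scaled_signals)
        scaled = compute_feature_vector(scaled_rep)
        for desc in ("mean", "rms", "std", "range"):
            assert scaled[f"mag_x__{desc}"] == pytest.approx(2 * base[f"mag_x__{desc}"], rel=1e-9)
        for desc in ("variance", "energy"):
            assert scaled[f"mag_x__{desc}"] == pytest.approx(4 * base[f"mag_x__{desc}"], rel=1e-9)
        untouched = [i for i, n in enumerate(FEATURE_NAMES) if not n.startswith("mag_x__")]
        np.testing.assert_array_equal(scaled.values[untouched], base.values[untouched])

    @pytest.mark.parametrize("shift", [-1.5, 2.25])
    def test_shift_property(self, rng, shift):
        x = rng.normal(size=256)
        shifted = x + shift
        for desc in ("mean", "median", "p25", "p75", "max", "min"):
            assert descriptor(desc, shifted) == pytest.approx(descriptor(desc, x) + shift, rel=1e-9, abs=1e-9)
        for desc in ("std", "variance", "range", "skewness", "kurtosis", "level_crossing_rate"):
            assert descriptor(desc, shifted) == pytest.approx(descriptor(desc, x), rel=1e-7, abs=1e-9)
        # rms / energy change per definition
        assert descriptor("energy", shifted) == pytest.approx(
            descriptor("energy", x) + 2 * shift * x.sum() + len(x) * shift**2, rel=1e-9
        )


class TestFeatureMatrix:
    def test_forty_rep_matrix_shape_and_labels(self, labeled_db):
        matrix, labels, keys = build_feature_matrix(labeled_db, "squat")
        assert matrix.shape == (40, 306)
        assert labels == [labeled_db.get(k).label for k in keys]
        assert keys == labeled_db.keys()

    def test_removing_one_rep_removes_one_row(self, labeled_db):
        import copy

        db = copy.deepcopy(labeled_db)
        victim = db.keys()[3]
        db.remove_rep(victim)
        matrix, _, keys = build_feature_matrix(db, "squat")
        assert matrix.shape == (39, 306)
        assert victim not in keys

    def test_missing_exercise(self, labeled_db):
        with pytest.raises(KeyError):
            build_feature_matrix(labeled_db, "bench press")
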