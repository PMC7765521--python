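"""Feature extraction: literal-equation oracles, worked examples, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sozloc import FeatureConfig, PEConfig, SpectralConfig, feature_matrix, feature_vector
from sozloc.features import (
    FEATURE_NAMES,
    cv,
    dasd,
    fi,
    ld,
    mav,
    mmav,
    mmav2,
    permutation_entropy,
    rms,
    spectral_entropies,
    var,
)

import oracles


class TestWorkedExamples:
    def test_cv_two_points(self):
        assert cv([2, 4]) == pytest.approx(1 / 3)

    def test_cv_constant_is_zero(self):
        assert cv([5, 5, 5]) == 0.0

    def test_cv_zero_mean_policy(self):
        with pytest.warns(UserWarning, match="zero-mean"):
            assert cv([-1, 1]) == 0.0

    def test_cv_positive_scale_invariance(self, rng):
        x = rng.random(50) + 1.0
        assert cv(3 * x) == pytest.approx(cv(x))

    def test_fi(self):
        assert fi([1, 3, 2]) == pytest.approx(1.5)
        assert fi([7, 7, 7, 7]) == 0.0
        x = np.arange(10.0)
        assert fi(x + 100.0) == pytest.approx(fi(x))

    def test_var(self):
        assert var([2, 4]) == pytest.approx(2.0)
        assert var([3, 3, 3]) == 0.0

    def test_var_quadratic_scaling(self, rng):
        x = rng.standard_normal(40)
        assert var(5 * x) == pytest.approx(25 * var(x))

    def test_rms(self):
        assert rms([3, -4]) == pytest.approx(math.sqrt(12.5))
        assert rms([0, 0, 0]) == 0.0

    def test_dasd(self):
        assert dasd([1, 3, 2]) == pytest.approx(math.sqrt(2.5))
        assert dasd([4, 4]) == 0.0

    def test_dasd_is_rms_of_diff_up_to_divisor(self, rng):
        x = rng.standard_normal(30)
        d = np.diff(x)
        assert dasd(x) == pytest.approx(math.sqrt((d**2).sum() / (len(x) - 1)))

    def test_mav(self):
        assert mav([1, -1, 2, -2]) == pytest.approx(1.5)
        assert mav([-3, -3]) == mav([3, 3])

    def test_mmav_window(self):
        # L=4: weights 1,1,1,0.5 (1-based i in [1,3])
        assert mmav([1, 1, 1, 1]) == pytest.approx(0.875)

    def test_mmav2_window_as_printed(self):
        # L=4: weights 1,1,1, 4*(4-4)/4=0
        assert mmav2([1, 1, 1, 1]) == pytest.approx(0.75)

    def test_mmav2_eight_ones_matches_literal_weights(self):
        x = [1.0] * 8
        assert mmav2(x) == pytest.approx(oracles.oracle_mmav2(x), rel=1e-12)

    def test_mmav2_abs_weight_variant(self):
        x = [0, 0, 0, 0, 0, 0, 1.0, 1.0]  # only the upper ramp is exercised
        assert mmav2(x, abs_weights=True) == pytest.approx(oracles.oracle_mmav2(x, True))
        assert mmav2(x, abs_weights=True) >= mmav2(x)

    def test_ld_geometric_mean(self):
        assert ld([1, 1, 1]) == pytest.approx(1.0)
        assert ld([2, 8]) == pytest.approx(4.0)

    def test_ld_zero_sample_stays_finite(self):
        value = ld([0.0, 1.0])
        assert 0 < value < 1 and math.isfinite(value)

    def test_pe_monotone_sequence_is_zero(self):
        assert permutation_entropy(np.arange(20.0)) == 0.0

    def test_pe_uniform_pattern_sequence(self):
        # all 6 ordinal patterns (m=3, tau=1) occur exactly once
        x = np.array([5, 4, 5, 8, 2, 7, 6, 0], dtype=float)
        assert permutation_entropy(x) == pytest.approx(math.log2(6))

    def test_pe_all_ties_is_zero(self):
        assert permutation_entropy(np.zeros(10)) == 0.0

    def test_pe_too_short_raises(self):
        with pytest.raises(ValueError):
            permutation_entropy([1.0, 2.0], PEConfig(m=3, tau=1))

    def test_spectral_single_tone(self):
        # power concentrated in one bin -> both entropies 0
        t = np.arange(64)
        x = np.sin(2 * np.pi * 8 * t / 64)
        she, re = spectral_entropies(x)
        assert she == pytest.approx(0.0, abs=1e-9)
        assert re == pytest.approx(0.0, abs=1e-9)

    def test_spectral_zero_power_policy(self):
        with pytest.warns(UserWarning, match="zero total power"):
            assert spectral_entropies(np.zeros(32)) == (0.0, 0.0)

    def test_spectral_uniform_closed_form(self):
        # a unit impulse has a perfectly flat spectrum: ShE = RE = ln(n_bins)
        x = np.zeros(33)
        x[0] = 1.0
        she, re = spectral_entropies(x)
        n_bins = 17
        assert she == pytest.approx(math.log(n_bins))
        assert re == pytest.approx(math.log(n_bins))


FEATURE_ORACLES = {
    "CV": oracles.oracle_cv,
    "FI": oracles.oracle_fi,
    "Var": oracles.oracle_var,
    "RMS": oracles.oracle_rms,
    "DASD": oracles.oracle_dasd,
    "MAV": oracles.oracle_mav,
    "MMAV": oracles.oracle_mmav,
    "MMAV2": oracles.oracle_mmav2,
    "LD": oracles.oracle_ld,
    "PE": oracles.oracle_pe,
}


class TestOracleEquivalence:
    """Every feature matches a literal loop evaluation of its equation."""

    @pytest.mark.parametrize("name", FEATURE_NAMES)
    def test_hundred_random_vectors(self, name):
        rng = np.random.default_rng(777)
        col = FEATURE_NAMES.index(name)
        for _ in range(100):
            L = int(rng.integers(20, 60))
            x = rng.standard_normal(L) * rng.uniform(0.5, 20)
            if name == "CV":
                x += rng.uniform(1, 5)  # keep the mean away from zero
            got = feature_vector(x)[col]
            if name in FEATURE_ORACLES:
                want = FEATURE_ORACLES[name](list(x))
            else:
                want = oracles.oracle_spectral(list(x))[0 if name == "ShE" else 1]
            assert got == pytest.approx(want, rel=1e-10, abs=1e-12), name

    def test_batch_matches_scalar_path(self, rng):
        Y = rng.standard_normal((7, 300))
        batch = feature_matrix(Y)
        scalar = np.stack([feature_vector(row) for row in Y])
        np.testing.assert_allclose(batch, scalar, rtol=1e-9, atol=1e-12)

    def test_batch_generic_pe_parameters(self, rng):
        cfg = FeatureConfig(pe=PEConfig(m=4, tau=2))
        Y = rng.standard_normal((3, 200))
        batch = feature_matrix(Y, cfg)
        for i, row in enumerate(Y):
            assert batch[i, 9] == pytest.approx(oracles.oracle_pe(list(row), m=4, tau=2))


class TestScaleAndShiftBehavior:
    """Declared amplitude behavior of each feature."""

    LINEAR = ["FI", "RMS", "DASD", "MAV", "MMAV", "MMAV2", "LD"]
    INVARIANT = ["CV", "PE", "ShE", "RE"]

    @pytest.mark.parametrize("name", LINEAR)
    def test_linear_amplitude_scaling(self, name, rng):
        x = rng.standard_normal(100)
        i = FEATURE_NAMES.index(name)
        v1, v3 = feature_vector(x)[i], feature_vector(3 * x)[i]
        assert v3 == pytest.approx(3 * v1, rel=1e-8)

    def test_variance_quadratic_scaling(self, rng):
        x = rng.standard_normal(100)
        i = FEATURE_NAMES.index("Var")
        assert feature_vector(3 * x)[i] == pytest.approx(9 * feature_vector(x)[i], rel=1e-8)

    @pytest.mark.parametrize("name", INVARIANT)
    def test_amplitude_scale_invariance(self, name, rng):
        x = rng.standard_normal(100) + 5.0  # positive mean for CV
        i = FEATURE_NAMES.index(name)
        assert feature_vector(2.5 * x)[i] == pytest.approx(feature_vector(x)[i], rel=1e-8)


class TestVectorContract:
    def test_order_and_length(self, rng):
        v = feature_vector(rng.standard_normal(64))
        assert v.shape == (len(FEATURE_NAMES),) == (12,)
        assert np.isfinite(v).all()

    def test_all_zero_signal_policy(self):
        with pytest.warns(UserWarning):
            v = feature_vector(np.zeros(40))
        expected = np.zeros(12)
        expected[FEATURE_NAMES.index("LD")] = 1e-12  # epsilon floor
        np.testing.assert_allclose(v, expected, atol=1e-15)

    def test_determinism(self, rng):
        x = rng.standard_normal(128)
        np.testing.assert_array_equal(feature_vector(x), feature_vector(x.copy()))

    def test_invalid_spectral_gamma(self):
        with pytest.raises(Exception):
            SpectralConfig(gamma=1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-1e3, 1e3), min_size=8, max_size=64))
def test_feature_inequalities_hold(xs):
    """RMS >= MAV >= MMAV, PE and spectral entropies within their bounds."""
    x = np.array(xs)
    assert rms(x) >= mav(x) - 1e-9
    assert mmav(x) <= mav(x) + 1e-9
    pe = permutation_entropy(x)
    assert -1e-9 <= pe <= math.log2(6) + 1e-9
    she, re = spectral_entropies(x)
    assert re <= she + 1e-9  # Rényi order 2 never exceeds Shannon
    assert she >= -1e-9 and re >= -1e-9
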