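"""Probability-weighted moments, L-statistics and the descriptor layer."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hep2hos.features import FeatureVector
from hep2hos.lmoments import (
    LMomentLayer,
    l_statistics,
    lmoment_descriptor,
    pwm_betas,
)


def lmoments_direct(sample):
    """Independent oracle: the order-statistic definitions

        lambda_r = (1/r) C(n,r)^{-1} sum_j [alternating comb weights] x_(j)

    computed with exact integer binomial coefficients (math.comb), i.e.
    the average of the expected L-moment over all r-element subsets."""
    x = np.sort(np.asarray(sample, float))
    n = x.size
    out = []
    for r in range(1, 5):
        total = 0.0
        for j in range(1, n + 1):
            s = sum(
                (-1) ** k * math.comb(r - 1, k) * math.comb(j - 1, r - 1 - k) * math.comb(n - j, k)
                for k in range(r)
            )
            total += s * x[j - 1]
        out.append(total / (r * math.comb(n, r)))
    return np.array(out)


def lmoments_enumerated(sample):
    """Second oracle for tiny n: literal enumeration over all subsets."""
    x = np.sort(np.asarray(sample, float))
    n = x.size
    coeffs = {2: [-1, 1], 3: [1, -2, 1], 4: [-1, 3, -3, 1]}
    out = [x.mean()]
    for r in (2, 3, 4):
        acc = 0.0
        for combo in itertools.combinations(range(n), r):
            ordered = [x[i] for i in combo]
            acc += sum(c * v for c, v in zip(coeffs[r], ordered))
        out.append(acc / (r * math.comb(n, r)))
    return np.array(out)


def lmoments_from_betas(sample):
    b = pwm_betas(sample)
    return np.array(
        [
            b.beta0,
            2 * b.beta1 - b.beta0,
            6 * b.beta2 - 6 * b.beta1 + b.beta0,
            20 * b.beta3 - 30 * b.beta2 + 12 * b.beta1 - b.beta0,
        ]
    )


class TestPWMBetas:
    def test_worked_example_1234(self):
        b = pwm_betas([1, 2, 3, 4])
        assert b.beta0 == pytest.approx(2.5)
        assert b.beta1 == pytest.approx(5 / 3)
        assert b.beta2 == pytest.approx(1.25)
        assert b.beta3 == pytest.approx(1.0)

    def test_constant_sample_identity(self):
        b = pwm_betas([5, 5, 5, 5])
        assert b.beta0 == pytest.approx(5.0)
        assert 2 * b.beta1 - b.beta0 == pytest.approx(0.0, abs=1e-12)

    def test_unsorted_input_sorted_internally(self):
        a, b = pwm_betas([4, 1, 3, 2]), pwm_betas([1, 2, 3, 4])
        assert (a.beta0, a.beta1, a.beta2, a.beta3) == (b.beta0, b.beta1, b.beta2, b.beta3)

    def test_short_sample_rejected(self):
        with pytest.raises(ValueError):
            pwm_betas([1, 2, 3])


class TestLStatistics:
    def test_worked_example_1234(self):
        q = l_statistics([1, 2, 3, 4])
        assert q.l_mean == pytest.approx(2.5)
        assert q.l_scale_ratio == pytest.approx(1 / 3)
        assert q.l_skewness == pytest.approx(0.0, abs=1e-12)
        assert q.l_kurtosis == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("c", [2.0, -3.5])
    def test_constant_sample_convention(self, c):
        q = l_statistics([c] * 5)
        assert q.l_mean == pytest.approx(c, rel=1e-12)
        assert (q.l_scale_ratio, q.l_skewness, q.l_kurtosis) == (0, 0, 0)

    def test_translation_equivariance(self, rng):
        x = rng.normal(size=20)
        a, b = l_statistics(x), l_statistics(x + 10)
        assert b.l_mean == pytest.approx(a.l_mean + 10, abs=1e-9)
        # L2 itself is shift invariant, as are the skewness/kurtosis ratios
        la = lmoments_from_betas(x)
        lb = lmoments_from_betas(x + 10)
        assert lb[1] == pytest.approx(la[1], abs=1e-10)
        assert b.l_skewness == pytest.approx(a.l_skewness, abs=1e-9)
        assert b.l_kurtosis == pytest.approx(a.l_kurtosis, abs=1e-9)

    def test_scale_equivariance_positive_sample(self, rng):
        x = rng.random(15) + 0.5
        a, b = l_statistics(x), l_statistics(3.0 * x)
        assert b.l_mean == pytest.approx(3.0 * a.l_mean, rel=1e-12)
        assert b.l_scale_ratio == pytest.approx(a.l_scale_ratio, rel=1e-12)
        assert b.l_skewness == pytest.approx(a.l_skewness, rel=1e-12)
        assert b.l_kurtosis == pytest.approx(a.l_kurtosis, rel=1e-12)

    def test_beta_estimators_match_order_statistic_oracle(self):
        """200 seeded random samples, n in [4, 50]: the beta-based L1..L4
        agree with the direct order-statistic definitions to 1e-10."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            x = rng.normal(scale=rng.uniform(0.5, 5.0), size=n)
            assert np.max(np.abs(lmoments_from_betas(x) - lmoments_direct(x))) <= 1e-10

    def test_oracles_agree_with_each_other_at_tiny_n(self, rng):
        for _ in range(10):
            x = rng.normal(size=int(rng.integers(4, 9)))
            assert np.allclose(lmoments_direct(x), lmoments_enumerated(x), atol=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False, allow_infinity=False),
            min_size=4,
            max_size=40,
        )
    )
    def test_ratio_bounds_for_nonconstant_samples(self, xs):
        """Sample L-skewness lies in [-1, 1] and sample L-kurtosis is at
        most 1.  (No two-sided bound holds for L-kurtosis at small n:
        e.g. [0, 0, 1, 1] has t4 = -1.5.)"""
        x = np.asarray(xs)
        if np.ptp(x) == 0:
            return
        q = l_statistics(x)
        assert abs(q.l_skewness) <= 1 + 1e-9
        assert q.l_kurtosis <= 1 + 1e-9


class TestDescriptorLayer:
    def _fv(self, values, n_angles, n_slopes):
        return FeatureVector(np.asarray(values, float), n_angles, n_slopes)

    def test_per_slope_length(self, rng):
        fv = self._fv(rng.normal(size=90 * 256), 90, 256)
        assert lmoment_descriptor(fv, "per_slope").size == 1024

    def test_per_angle_length(self, rng):
        fv = self._fv(rng.normal(size=90 * 256), 90, 256)
        assert lmoment_descriptor(fv, "per_angle").size == 360

    def test_global_length(self, rng):
        fv = self._fv(rng.normal(size=90 * 256), 90, 256)
        assert lmoment_descriptor(fv, "global").size == 4

    def test_constant_blocks_zero_dispersion(self):
        vals = np.repeat(np.arange(6.0), 8)  # 6 angle blocks, constant each
        fv = self._fv(vals, 6, 8)
        d = lmoment_descriptor(fv, "per_angle").reshape(6, 4)
        assert np.allclose(d[:, 0], np.arange(6.0))
        assert np.allclose(d[:, 1:], 0.0)

    def test_small_group_rejected(self, rng):
        fv = self._fv(rng.normal(size=6), 3, 2)
        with pytest.raises(ValueError):
            lmoment_descriptor(fv, "per_angle")

    def test_layer_matches_descriptor_function(self, rng):
        X = rng.normal(size=(3, 12 * 16))
        layer = LMomentLayer(grouping="per_slope", n_slopes=16).fit(X)
        D = layer.transform(X)
        assert D.shape == (3, 64)
        fv = self._fv(X[0], 12, 16)
        assert np.allclose(D[0], lmoment_descriptor(fv, "per_slope"))

    def test_per_slope_invariant_to_angle_rotation(self, rng):
        """Cyclically shifting the angle axis (image rotation) leaves the
        per-slope descriptor unchanged."""
        A = rng.normal(size=(12, 16))  # angles x slopes
        layer = LMomentLayer(grouping="per_slope", n_slopes=16)
        d0 = layer.transform(A.ravel()[None, :])
        d1 = layer.transform(np.roll(A, 5, axis=0).ravel()[None, :])
        assert np.allclose(d0, d1, atol=1e-12)

    def test_fixed_blocks(self, rng):
        X = rng.normal(size=(2, 64))
        layer = LMomentLayer(grouping="fixed_blocks", block_size=8).fit(X)
        assert layer.transform(X).shape == (2, 32)
        with pytest.raises(ValueError):
            LMomentLayer(grouping="fixed_blocks", block_size=3).fit(X)
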