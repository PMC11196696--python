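"""Grayscale morphology against brute-force oracles and algebraic laws."""

import numpy as np
import pytest
from scipy.ndimage import grey_dilation, grey_erosion

from seismogait.morphology import StructuringElement, closing, ctf, dilate, erode, opening


def brute_erode(x, heights):
    """Independent oracle: explicit min loop with boundary clipping."""
    n, r = len(x), len(heights) // 2
    out = np.empty(n)
    for i in range(n):
        vals = [x[i + k] - heights[k + r] for k in range(-r, r + 1) if 0 <= i + k < n]
        out[i] = min(vals)
    return out


def brute_dilate(x, heights):
    n, r = len(x), len(heights) // 2
    out = np.empty(n)
    for i in range(n):
        vals = [x[i - k] + heights[k + r] for k in range(-r, r + 1) if 0 <= i - k < n]
        out[i] = max(vals)
    return out


def random_se(rng):
    radius_samples = int(rng.integers(0, 5))  # SE length 1..9
    shape = rng.choice(["flat", "spherical"])
    return StructuringElement(
        radius=max(radius_samples, 0.5) / 100.0 if radius_samples == 0 else radius_samples / 100.0,
        fs=100.0,
        shape=str(shape),
        height=float(rng.uniform(0.05, 1.5)),
    )


class TestAgainstBruteForce:
    def test_erode_dilate_match_oracle_on_random_signals(self, rng):
        for _ in range(50):
            x = rng.normal(size=int(rng.integers(9, 64)))
            se = random_se(rng)
            np.testing.assert_array_equal(erode(x, se).samples, brute_erode(x, se.heights))
            np.testing.assert_array_equal(dilate(x, se).samples, brute_dilate(x, se.heights))

    def test_compound_ops_match_composed_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(9, 40)))
            se = random_se(rng)
            op = brute_dilate(brute_erode(x, se.heights), se.heights)
            cl = brute_erode(brute_dilate(x, se.heights), se.heights)
            np.testing.assert_array_equal(opening(x, se).samples, op)
            np.testing.assert_array_equal(closing(x, se).samples, cl)
            np.testing.assert_array_equal(ctf(x, se).samples, x - 0.5 * (op + cl))

    def test_interior_matches_scipy_grey_morphology(self, rng):
        """Cross-check against scipy.ndimage away from the boundary."""
        x = rng.normal(size=200)
        se = StructuringElement(radius=0.04, fs=100.0, shape="spherical", height=0.7)
        r = se.half
        ero = grey_erosion(x, structure=se.heights, mode="nearest")
        dil = grey_dilation(x, structure=se.heights, mode="nearest")
        np.testing.assert_allclose(erode(x, se).samples[r:-r], ero[r:-r], atol=1e-12)
        np.testing.assert_allclose(dilate(x, se).samples[r:-r], dil[r:-r], atol=1e-12)


class TestHandExamples:
    def test_flat_se_on_spike(self, flat_se3):
        np.testing.assert_array_equal(erode([1, 5, 1], flat_se3).samples, [1, 1, 1])
        np.testing.assert_array_equal(dilate([1, 5, 1], flat_se3).samples, [5, 5, 5])

    def test_length_one_se_is_identity(self):
        se = StructuringElement(radius=0.004, fs=100.0, shape="flat")
        assert len(se) == 1
        x = np.array([3.0, -1.0, 2.0])
        np.testing.assert_array_equal(erode(x, se).samples, x)
        np.testing.assert_array_equal(dilate(x, se).samples, x)

    def test_constant_signal_shifts_by_peak_height(self):
        se = StructuringElement(radius=0.02, fs=100.0, shape="spherical", height=0.8)
        c = np.full(20, 3.0)
        np.testing.assert_allclose(erode(c, se).samples, 3.0 - 0.8)
        np.testing.assert_allclose(dilate(c, se).samples, 3.0 + 0.8)

    def test_opening_removes_spike_closing_fills_dip(self, flat_se3):
        spike = np.zeros(11)
        spike[5] = 2.0
        np.testing.assert_array_equal(opening(spike, flat_se3).samples, np.zeros(11))
        np.testing.assert_array_equal(closing(-spike, flat_se3).samples, np.zeros(11))

    def test_ctf_of_constant_is_zero(self, spherical_se):
        out = ctf(np.full(60, 7.5), spherical_se).samples
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_ctf_of_ramp_is_zero_in_interior_flat_se(self):
        se = StructuringElement(radius=0.03, fs=100.0, shape="flat")
        x = np.linspace(0.0, 5.0, 50)
        r = se.half
        np.testing.assert_allclose(ctf(x, se).samples[r:-r], 0.0, atol=1e-12)

    def test_ctf_nonnegative_peak_at_spike(self, flat_se3):
        x = np.zeros(15)
        x[7] = 1.0
        out = ctf(x, flat_se3).samples
        assert out.min() >= -1e-12
        assert np.argmax(out) == 7

    def test_se_longer_than_signal_rejected(self, spherical_se):
        with pytest.raises(ValueError, match="SE length"):
            erode(np.zeros(10), spherical_se)


class TestAlgebraicLaws:
    @pytest.mark.parametrize("shape", ["flat", "spherical"])
    def test_duality_idempotence_extensivity(self, rng, shape):
        for _ in range(30):
            x = rng.normal(size=40)
            se = StructuringElement(
                radius=float(rng.integers(1, 5)) / 100.0,
                fs=100.0,
                shape=shape,
                height=float(rng.uniform(0.1, 1.0)),
            )
            # duality: erosion is dilation of the reflected signal
            np.testing.assert_allclose(
                erode(x, se).samples, -dilate(-x, se).samples, atol=1e-12
            )
            op = opening(x, se).samples
            cl = closing(x, se).samples
            # idempotence
            np.testing.assert_allclose(opening(op, se).samples, op, atol=1e-12)
            np.testing.assert_allclose(closing(cl, se).samples, cl, atol=1e-12)
            # anti-extensivity / extensivity
            assert np.all(op <= x + 1e-12)
            assert np.all(cl >= x - 1e-12)

    def test_translation_covariance_interior(self, rng, spherical_se):
        x = rng.normal(size=120)
        shifted = np.roll(x, 7)
        r = spherical_se.half
        out = erode(x, spherical_se).samples
        out_shifted = erode(shifted, spherical_se).samples
        np.testing.assert_allclose(out_shifted[r + 7 : -r], np.roll(out, 7)[r + 7 : -r])


class TestStructuringElement:
    def test_default_se_discretization(self, spherical_se):
        assert len(spherical_se) == 41
        assert spherical_se.half == 20
        h = spherical_se.heights
        np.testing.assert_allclose(h, h[::-1])  # symmetric
        assert h[20] == pytest.approx(spherical_se.height)
        assert h[0] == pytest.approx(0.0)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            StructuringElement(shape="cubic")
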