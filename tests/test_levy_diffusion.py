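import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from levysmooth.levy_diffusion import (
    DiffusionParams,
    dft_oracle_diffuse,
    diffuse,
    diffuse_suite,
    frequency_grid,
    levy_multiplier,
)


class TestFrequencyGrid:
    def test_length_four_indices(self):
        k, l = frequency_grid(4, 4)
        assert sorted(k.ravel()) == [-2, -1, 0, 1]
        assert sorted(l.ravel()) == [-2, -1, 0, 1]

    @pytest.mark.parametrize("n", [2, 6, 16, 64])
    def test_half_open_range_and_single_zero(self, n):
        k, _ = frequency_grid(n, n)
        flat = k.ravel()
        assert flat.min() == -n // 2
        assert flat.max() == n // 2 - 1
        assert np.count_nonzero(flat == 0) == 1

    def test_native_ordering_matches_fft(self):
        k, l = frequency_grid(8, 6)
        assert np.array_equal(k.ravel(), np.fft.fftfreq(8, 1 / 8))
        assert np.array_equal(l.ravel(), np.fft.fftfreq(6, 1 / 6))

    def test_odd_dimension_directs_to_padding(self):
        with pytest.raises(ValueError, match="pad"):
            frequency_grid(5, 4)


class TestLevyMultiplier:
    def test_dc_is_one_any_parameters(self):
        for p in (0.1, 0.5, 1.0):
            for t in (0.0, 0.3, 5.0):
                assert levy_multiplier(8, 8, p, t)[0, 0] == 1.0

    def test_unit_radius_value(self):
        # at k^2+l^2 = 1 the exponent power is irrelevant: exp(-t)
        m = levy_multiplier(8, 8, 0.1, 0.5)
        assert m[1, 0] == pytest.approx(np.exp(-0.5), rel=1e-12)
        assert m[0, 1] == pytest.approx(0.606531, rel=1e-6)

    def test_frozen_scalar_evaluation(self):
        # (k,l)=(3,4): exp(-0.5 * 25**0.1), evaluated independently
        m = levy_multiplier(16, 16, 0.1, 0.5)
        assert m[3, 4] == pytest.approx(np.exp(-0.5 * 25**0.1), rel=1e-12)
        assert m[3, 4] == pytest.approx(0.501644, abs=5e-6)

    def test_range_isotropy_and_t_zero(self):
        m = levy_multiplier(12, 12, 0.3, 0.7)
        assert np.all(m > 0) and np.all(m <= 1)
        # isotropy: value depends only on k^2 + l^2
        assert m[2, 3] == m[3, 2] == m[-2, 3] == m[2, -3]
        assert np.all(levy_multiplier(12, 12, 0.3, 0.0) == 1.0)

    def test_strictly_decreasing_in_t_off_dc(self):
        m1 = levy_multiplier(8, 8, 0.1, 0.2)
        m2 = levy_multiplier(8, 8, 0.1, 0.4)
        off_dc = np.ones((8, 8), dtype=bool)
        off_dc[0, 0] = False
        assert np.all(m2[off_dc] < m1[off_dc])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            levy_multiplier(8, 8, 0.1, -0.1)

    def test_gaussian_limit_exact(self):
        """At p=1 the multiplier is exactly the discrete heat kernel."""
        k, l = frequency_grid(16, 16)
        for t in (0.1, 0.5):
            expected = np.exp(-t * (k * k + l * l))
            assert np.array_equal(levy_multiplier(16, 16, 1.0, t), expected)

    def test_heavy_tail_dominates_gaussian(self):
        """The p=0.1 multiplier strictly exceeds the Gaussian one wherever
        k^2+l^2 > 1: heavy-tailed smoothing attenuates high frequencies far
        more gently."""
        k, l = frequency_grid(32, 32)
        r2 = (k * k + l * l).astype(float)
        for t in (0.1, 0.3, 0.5):
            levy = levy_multiplier(32, 32, 0.1, t)
            gauss = levy_multiplier(32, 32, 1.0, t)
            sel = r2 > 1
            assert np.all(levy[sel] > gauss[sel])
            assert np.array_equal(levy[r2 == 1], gauss[r2 == 1])


class TestDiffuse:
    def test_time_zero_identity_exact(self, rng):
        img = rng.uniform(0, 255, (8, 10))
        assert np.array_equal(diffuse(img, 0.1, 0.0), img)

    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 99.0)
        assert np.allclose(diffuse(img, 0.1, 0.4), img, atol=1e-10)

    def test_mean_preserved_and_l2_nonincreasing(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        prev = np.linalg.norm(img)
        for t in (0.1, 0.2, 0.4, 0.8):
            out = diffuse(img, 0.1, t)
            assert out.mean() == pytest.approx(img.mean(), rel=1e-10)
            norm = np.linalg.norm(out)
            assert norm <= prev + 1e-9
            prev = norm

    def test_odd_dimensions_rejected(self):
        with pytest.raises(ValueError, match="even"):
            diffuse(np.zeros((5, 8)), 0.1, 0.1)

    @given(seed=st.integers(0, 2**16), p=st.sampled_from([0.1, 0.5, 1.0]))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_semigroup_property(self, seed, p):
        """Evolving by t1 then t2 equals evolving by t1 + t2."""
        img = np.random.default_rng(seed).uniform(0, 255, (10, 8))
        t1, t2 = 0.15, 0.25
        two_step = diffuse(diffuse(img, p, t1), p, t2)
        one_step = diffuse(img, p, t1 + t2)
        assert np.max(np.abs(two_step - one_step)) <= 1e-9 * max(
            1.0, np.max(np.abs(one_step))
        )

    def test_spectral_monotonicity(self, rng):
        """Every Fourier magnitude decays as t grows."""
        img = rng.uniform(0, 255, (12, 12))
        s1 = np.abs(np.fft.fft2(diffuse(img, 0.1, 0.2)))
        s2 = np.abs(np.fft.fft2(diffuse(img, 0.1, 0.5)))
        assert np.all(s2 <= s1 + 1e-8)


class TestOracleAgreement:
    def test_matches_direct_summation_on_random_images(self):
        """The FFT path reproduces the brute-force DFT evolution to 1e-10
        relative error over 50 random 8x8 images at several (p, t)."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(50):
            img = rng.uniform(0, 255, (8, 8))
            for p in (0.1, 0.5, 1.0):
                for t in (0.0, 0.3):
                    fast = diffuse(img, p, t)
                    slow = dft_oracle_diffuse(img, p, t)
                    scale = max(1.0, np.max(np.abs(slow)))
                    worst = max(worst, np.max(np.abs(fast - slow)) / scale)
        assert worst < 1e-10

    def test_oracle_time_zero_identity(self, rng):
        img = rng.uniform(0, 255, (6, 8))
        assert np.allclose(dft_oracle_diffuse(img, 0.1, 0.0), img, atol=1e-10)

    def test_impulse_response_symmetric_blur(self):
        img = np.zeros((8, 8))
        img[4, 4] = 255.0
        out = dft_oracle_diffuse(img, 1.0, 0.1)
        assert np.allclose(out, diffuse(img, 1.0, 0.1), atol=1e-10)
        # symmetry of the Green's function about the impulse
        assert out[3, 4] == pytest.approx(out[5, 4], rel=1e-10)
        assert out[4, 3] == pytest.approx(out[4, 5], rel=1e-10)
        # once the multiplier has decayed at the band edge the discrete
        # kernel is effectively a sampled Gaussian and hence nonnegative;
        # at small t the band-limited kernel necessarily rings
        late = dft_oracle_diffuse(img, 1.0, 1.0)
        assert late.min() > -1e-9

    def test_oracle_size_cap(self):
        with pytest.raises(ValueError, match="32"):
            dft_oracle_diffuse(np.zeros((34, 34)), 0.1, 0.1)


class TestDiffuseSuite:
    def test_default_times(self):
        params = DiffusionParams()
        assert params.frame_times == pytest.approx((0.0, 0.1, 0.2, 0.3, 0.4, 0.5))

    def test_first_frame_is_input_exactly(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        suite = diffuse_suite(img, DiffusionParams())
        assert np.array_equal(suite.frames[0][1], img)

    def test_l2_norms_nonincreasing_along_suite(self, rng):
        img = rng.uniform(0, 255, (16, 16))
        suite = diffuse_suite(img, DiffusionParams())
        norms = [np.linalg.norm(f) for _, f in suite.frames]
        assert np.all(np.diff(norms) <= 1e-9)

    def test_frame_count_matches_params(self, rng):
        img = rng.uniform(0, 255, (8, 8))
        suite = diffuse_suite(img, DiffusionParams(n_frames=4, t_max=0.3))
        assert len(suite) == 4
        assert suite.times == pytest.approx((0.0, 0.1, 0.2, 0.3))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            DiffusionParams(p=0.0)
        with pytest.raises(ValueError):
            DiffusionParams(t_max=-1.0)
        with pytest.raises(ValueError):
            DiffusionParams(n_frames=1)
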