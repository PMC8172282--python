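import numpy as np
import pytest
from scipy import ndimage

from retina_frangi import (
    ScaleSet,
    EigenField,
    gaussian_smooth,
    hessian_at_scale,
    eigen2x2,
    improved_response,
    multiscale_response,
    traditional_vesselness,
)
from retina_frangi.frangi import _gauss_kernels, HessianField


def gaussian_bar(n=128, sigma=3.0, depth=0.4, base=0.8, axis=0):
    """Dark straight bar of Gaussian cross-section along the given axis."""
    y = np.arange(n, dtype=float) - n // 2
    profile = depth * np.exp(-(y ** 2) / (2 * sigma ** 2))
    img = base - (profile[:, None] if axis == 0 else profile[None, :])
    return img * np.ones((n, n))


class TestGaussianSmooth:
    def test_dc_preservation(self):
        img = np.full((32, 32), 0.63)
        assert np.allclose(gaussian_smooth(img, 2.0), 0.63, atol=1e-12)

    @pytest.mark.parametrize("s", [1.0, 2.0, 3.0])
    def test_impulse_central_value(self, s):
        img = np.zeros((129, 129))
        img[64, 64] = 1.0
        out = gaussian_smooth(img, s)
        assert abs(out[64, 64] - 1 / (2 * np.pi * s * s)) < 0.01 / (
            2 * np.pi * s * s)

    def test_separable_equals_full_2d_convolution(self, rng):
        img = rng.uniform(size=(16, 16))
        s = 1.5
        g, _, _ = _gauss_kernels(s)
        full = ndimage.convolve(img, np.outer(g, g), mode="reflect")
        assert np.abs(gaussian_smooth(img, s) - full).max() < 1e-10

    def test_nonpositive_scale_errors(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((8, 8)), 0.0)


class TestHessian:
    def test_constant_image_zero_derivatives(self):
        h = hessian_at_scale(np.full((32, 32), 0.4), 2.0)
        for f in (h.ixx, h.ixy, h.iyy):
            assert np.abs(f).max() < 1e-12

    @pytest.mark.parametrize("s", [1.0, 2.0, 4.0])
    def test_quadratic_ramp_analytic(self, s):
        x = np.arange(96, dtype=float)
        img = np.tile(x ** 2, (96, 1))
        h = hessian_at_scale(img, s)
        lo, hi = 40, 56
        assert np.allclose(h.ixx[lo:hi, lo:hi], 2 * s * s, rtol=0.01)
        assert np.abs(h.ixy[lo:hi, lo:hi]).max() < 1e-8 * (2 * s * s)
        assert np.abs(h.iyy[lo:hi, lo:hi]).max() < 1e-8 * (2 * s * s)

    def test_symmetric_blob_zero_cross_derivative_at_center(self):
        n = 65
        y, x = np.mgrid[0:n, 0:n] - n // 2
        img = np.exp(-(x ** 2 + y ** 2) / (2 * 16.0))
        h = hessian_at_scale(img, 2.0)
        assert abs(h.ixy[n // 2, n // 2]) < 1e-8

    def test_nonpositive_scale_errors(self):
        with pytest.raises(ValueError):
            hessian_at_scale(np.zeros((8, 8)), -1.0)


class TestEigen:
    def test_diagonal_field(self):
        h = HessianField(ixx=np.array([[3.0]]), ixy=np.array([[0.0]]),
                         iyy=np.array([[1.0]]), scale=1.0)
        e = eigen2x2(h)
        assert e.lam1[0, 0] == 3.0 and e.lam2[0, 0] == 1.0

    def test_magnitude_tie_prefers_larger_signed(self):
        h = HessianField(ixx=np.array([[0.0]]), ixy=np.array([[1.0]]),
                         iyy=np.array([[0.0]]), scale=1.0)
        e = eigen2x2(h)
        assert e.lam1[0, 0] == 1.0 and e.lam2[0, 0] == -1.0

    def test_random_matrices_match_characteristic_polynomial(self, rng):
        """Quadratic-formula oracle plus trace/determinant conservation on
        1000 random symmetric matrices."""
        ixx, ixy, iyy = rng.normal(size=(3, 1000))
        h = HessianField(ixx=ixx, ixy=ixy, iyy=iyy, scale=1.0)
        e = eigen2x2(h)
        # ordering contract
        assert np.all(np.abs(e.lam1) >= np.abs(e.lam2))
        tr, det = ixx + iyy, ixx * iyy - ixy ** 2
        scale = np.maximum(1.0, np.abs(tr))
        assert np.abs(e.lam1 + e.lam2 - tr).max() / scale.max() < 1e-9
        scale_d = np.maximum(1.0, np.abs(det))
        assert (np.abs(e.lam1 * e.lam2 - det) / scale_d).max() < 1e-9
        # roots of λ² − tr·λ + det = 0
        disc = np.sqrt(tr ** 2 - 4 * det)
        roots_hi = (tr + disc) / 2
        roots_lo = (tr - disc) / 2
        got = np.sort(np.stack([e.lam1, e.lam2]), axis=0)
        want = np.sort(np.stack([roots_hi, roots_lo]), axis=0)
        assert np.allclose(got, want, atol=1e-9, rtol=1e-9)


class TestImprovedResponse:
    def test_zero_lam2_gives_unit_response(self):
        e = EigenField(np.array([5.0]), np.array([0.0]))
        assert improved_response(e, 2.0)[0] == 1.0

    def test_equal_eigenvalues_point_value(self):
        e = EigenField(np.array([2.0]), np.array([2.0]))
        expect = np.exp(-(np.pi / 4) ** 2)
        assert abs(improved_response(e, 1.0)[0] - expect) < 1e-12

    def test_bright_ridge_suppressed(self):
        e = EigenField(np.array([-3.0]), np.array([1.0]))
        assert improved_response(e, 1.0)[0] == 0.0

    def test_floor_zeroes_negligible_lam1(self):
        e = EigenField(np.array([1e-12, 5e-11]), np.array([0.0, 0.0]))
        assert np.all(improved_response(e, 1.0) == 0.0)

    def test_output_in_unit_interval(self, rng):
        lam1 = rng.normal(scale=30, size=500)
        lam2 = rng.normal(scale=30, size=500)
        out = improved_response(EigenField(lam1, lam2), 1.5)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_nonpositive_scale_errors(self):
        with pytest.raises(ValueError):
            improved_response(EigenField(np.ones(1), np.ones(1)), 0.0)


class TestMultiscale:
    def test_singleton_scale_equals_single_response(self, rng):
        img = rng.uniform(size=(32, 32))
        got = multiscale_response(img, ScaleSet(2, 2, 1), gain=1.0,
                                  normalize=False)
        e = eigen2x2(hessian_at_scale(img, 2.0))
        want = improved_response(e, 2.0)
        assert np.array_equal(got, want)

    def test_max_dominates_per_scale_responses(self, rng):
        img = rng.uniform(size=(32, 32))
        ss = ScaleSet(1, 3, 1)
        got = multiscale_response(img, ss, gain=255.0, normalize=False)
        for s in ss.values():
            e = eigen2x2(hessian_at_scale(img, s))
            f = improved_response(
                EigenField(255 * e.lam1, 255 * e.lam2), s)
            assert np.all(got >= f - 1e-15)

    def test_scale_attribution_matches_bruteforce_oracle(self):
        """Per-pixel argmax scale equals a direct scan over scales with the
        same λ1 tie-break rule."""
        img = gaussian_bar(96, sigma=3.0)
        ss = ScaleSet(1, 6, 1)
        resp, sc = multiscale_response(img, ss, gain=255.0, lam_floor=10.0,
                                       normalize=False, return_scales=True)
        best = np.full(img.shape, -np.inf)
        best_l1 = np.full(img.shape, -np.inf)
        best_s = np.zeros(img.shape)
        for s in ss.values():
            e = eigen2x2(hessian_at_scale(img, s))
            f = improved_response(EigenField(255 * e.lam1, 255 * e.lam2),
                                  s, lam_floor=10.0)
            upd = (f > best) | ((f == best) & (255 * e.lam1 > best_l1))
            best = np.where(upd, f, best)
            best_l1 = np.where(upd, 255 * e.lam1, best_l1)
            best_s = np.where(upd, s, best_s)
        assert np.array_equal(resp, best)
        assert np.array_equal(sc, best_s)

    def test_rotation_equivariance_quarter_turn(self):
        img = gaussian_bar(64, sigma=2.0, axis=0)
        ss = ScaleSet(1, 4, 1)
        a = multiscale_response(np.rot90(img), ss, normalize=False)
        b = np.rot90(multiscale_response(img, ss, normalize=False))
        assert np.abs(a - b).max() < 1e-6

    def test_scale_monotonicity_on_tapered_bar(self):
        """Response at the matched scale beats the response at 4× the bar
        half-width (finite bar, so λ2 is small but nonzero)."""
        n, w = 160, 2.0
        y, x = np.mgrid[0:n, 0:n] - n // 2
        img = 1.0 - 0.5 * np.exp(-(y ** 2) / (2 * w ** 2)) * np.exp(
            -(x ** 2) / (2 * (10 * w) ** 2))
        c = n // 2

        def resp_at(s):
            e = eigen2x2(hessian_at_scale(img, s))
            f = improved_response(EigenField(255 * e.lam1, 255 * e.lam2), s)
            return f[c, c]

        assert resp_at(w) > resp_at(4 * w)

    def test_invariant_to_constant_offset(self, rng):
        img = 0.3 * rng.uniform(size=(32, 32))
        a = multiscale_response(img, ScaleSet(1, 2, 1), normalize=False)
        b = multiscale_response(img + 0.5, ScaleSet(1, 2, 1),
                                normalize=False)
        assert np.abs(a - b).max() < 1e-9

    def test_deterministic(self, rng):
        img = rng.uniform(size=(48, 48))
        a = multiscale_response(img, ScaleSet())
        b = multiscale_response(img, ScaleSet())
        assert np.array_equal(a, b)

    def test_invalid_scale_set(self):
        with pytest.raises(ValueError):
            ScaleSet(3, 2, 0.5)
        with pytest.raises(ValueError):
            ScaleSet(1, 2, -1)


class TestTraditionalVesselness:
    def test_constant_image_zero(self):
        out = traditional_vesselness(np.full((32, 32), 0.5), ScaleSet(1, 2, 1))
        assert np.all(out == 0.0)

    def test_bar_centerline_exceeds_background(self):
        img = gaussian_bar(96, sigma=3.0)
        out = traditional_vesselness(img, ScaleSet(1, 6, 1), normalize=False)
        assert out[48, 48] > out[10, 48]

    def test_range_contract(self, rng):
        img = rng.uniform(size=(48, 48))
        out = traditional_vesselness(img, ScaleSet(1, 3, 1))
        assert out.min() >= 0.0 and out.max() <= 1.0
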