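import numpy as np
import pytest
from scipy import ndimage

from gaborvessel.gabor_bank import (
    GaborBankConfig,
    build_gabor_kernel,
    gabor_max_response,
    gabor_responses,
)

DEFAULTS = GaborBankConfig()


def gaussian_line_image(size: int, normal_angle: float, width: float = 1.5) -> np.ndarray:
    """Bright field with a dark smooth-profile line through the centre whose
    normal points along ``normal_angle`` (the line itself runs perpendicular)."""
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - (size - 1) / 2
    x = xx - (size - 1) / 2
    d = np.cos(normal_angle) * x + np.sin(normal_angle) * y
    return 0.8 - 0.5 * np.exp(-(d**2) / (2 * width**2))


class TestKernel:
    def test_point_reflection_and_quarter_turn_symmetries(self):
        # phi_u = pi u / n spans half a turn, so point reflection of a
        # kernel (z -> -z) flips the plane-wave sign: it equals the
        # conjugate kernel; and u -> u + n/2 is a quarter-turn rotation
        # of the kernel array.
        n = DEFAULTS.n_orientations
        for u in range(n // 2):
            k_u = build_gabor_kernel(DEFAULTS, u)
            assert np.allclose(np.flip(k_u, axis=(0, 1)), np.conj(k_u), atol=1e-12)
            k_quarter = build_gabor_kernel(DEFAULTS, (u + n // 2) % n)
            assert np.allclose(k_quarter, np.rot90(k_u, 3), atol=1e-10)

    def test_center_value_matches_closed_form(self):
        # odd kernel so the grid contains z = 0 exactly
        cfg = GaborBankConfig(kernel_width=31, kernel_height=31)
        k = build_gabor_kernel(cfg, 0)
        knorm = cfg.wavenumber(0)
        expected = (knorm**2 / cfg.sigma) * (1.0 - np.exp(-cfg.sigma**2 / 2.0))
        assert k[15, 15] == pytest.approx(expected, rel=1e-12)

    def test_dc_compensation_keeps_kernel_sum_small(self):
        # The exp(-sigma^2/2) term cancels the DC value exactly in the
        # continuum; on the pixel grid a sampling (aliasing) residue of a
        # few percent of the peak remains at the default parameters.
        for u in range(DEFAULTS.n_orientations):
            k = build_gabor_kernel(DEFAULTS, u)
            assert abs(k.sum()) < 5e-2 * np.abs(k).max()

    def test_out_of_range_indices_rejected(self):
        with pytest.raises(ValueError):
            build_gabor_kernel(DEFAULTS, DEFAULTS.n_orientations)
        with pytest.raises(ValueError):
            build_gabor_kernel(DEFAULTS, 0, v=3)

    def test_scale_index_shrinks_wavenumber(self):
        cfg = GaborBankConfig(scales=(0, 1, 2))
        ks = [cfg.wavenumber(v) for v in (0, 1, 2)]
        assert ks[1] == pytest.approx(ks[0] / np.sqrt(2))
        assert ks[2] == pytest.approx(ks[0] / 2)


class TestResponse:
    def test_constant_image_gives_zero_response(self):
        out = gabor_max_response(np.full((70, 70), 0.6), DEFAULTS)
        assert np.array_equal(out, np.zeros((70, 70)))

    def test_output_range_and_shape(self, small_phantom):
        img, _, fov = small_phantom
        out = gabor_max_response(img.green, DEFAULTS, fov=fov)
        assert out.shape == img.green.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_offset_invariance_of_rescaled_response(self, rng):
        # DC compensation: adding a constant offset perturbs the rescaled
        # response only through the few-percent sampling residue of the
        # kernel sum (see test_dc_compensation_keeps_kernel_sum_small).
        img = 0.3 + 0.2 * rng.random((72, 72))
        base = gabor_max_response(img, DEFAULTS)
        shifted = gabor_max_response(img + 0.25, DEFAULTS)
        assert np.abs(base - shifted).max() < 5e-2

    def test_doubling_image_doubles_raw_response(self, rng):
        # homogeneity of convolution + magnitude; the min-max rescaled
        # output is exactly invariant under the scaling
        img = 0.4 + 0.1 * rng.random((72, 72))
        raw = gabor_responses(img, DEFAULTS)
        raw2 = gabor_responses(2 * img, DEFAULTS)
        assert np.allclose(raw2, 2 * raw, rtol=1e-10, atol=1e-12)
        assert np.allclose(
            gabor_max_response(img, DEFAULTS),
            gabor_max_response(2 * img, DEFAULTS),
            atol=1e-10,
        )

    @pytest.mark.parametrize("u0", range(8))
    def test_orientation_recovery(self, u0):
        img = gaussian_line_image(96, DEFAULTS.orientation_angle(u0))
        responses = gabor_responses(img, DEFAULTS)
        winner = responses.argmax(axis=0)
        yy, xx = np.mgrid[0:96, 0:96]
        y, x = yy - 47.5, xx - 47.5
        phi = DEFAULTS.orientation_angle(u0)
        on_line = (np.abs(np.cos(phi) * x + np.sin(phi) * y) <= 1.0) & (
            np.sqrt(x**2 + y**2) < 30
        )
        assert np.mean(winner[on_line] == u0) > 0.5

    def test_image_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            gabor_max_response(np.zeros((32, 32)), DEFAULTS)

    def test_kernel_bank_export(self, tmp_path):
        import tifffile

        from gaborvessel.gabor_bank import export_kernel_bank

        path = tmp_path / "bank.tiff"
        export_kernel_bank(path, DEFAULTS)
        pages = tifffile.imread(path)
        # one real + one imaginary page per kernel
        assert pages.shape == (2 * DEFAULTS.n_orientations, 60, 60)
        assert np.allclose(pages[0], build_gabor_kernel(DEFAULTS, 0).real, atol=1e-6)

    def test_fft_convolution_matches_direct(self, rng):
        # implementation freedom clause: FFT and spatial convolution must
        # agree to 1e-6
        from gaborvessel.gabor_bank import _convolve_reflect

        img = rng.random((64, 64))
        cfg = GaborBankConfig(kernel_width=15, kernel_height=15)
        k = build_gabor_kernel(cfg, 3)
        fft_out = _convolve_reflect(img, k)
        direct = ndimage.convolve(img, k.real, mode="mirror") + 1j * ndimage.convolve(
            img, k.imag, mode="mirror"
        )
        assert np.abs(fft_out - direct).max() < 1e-6
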