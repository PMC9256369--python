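import numpy as np
import pytest

from gaborvessel.enhance_classic import (
    GcadwConfig,
    HomomorphicConfig,
    UnsharpConfig,
    compute_weighted_cdf,
    gcadw_enhance,
    homomorphic_enhance,
    homomorphic_transfer,
    jeh_equalize,
    jeh_equalized_level,
    jeh_workspace,
    neighborhood_mean,
    unsharp_enhance,
)
from oracles import gcadw_map_oracle, jeh_oracle


class TestWeightedCdf:
    def test_single_occupied_level(self):
        hist = np.zeros(256)
        hist[100] = 50
        cdf = compute_weighted_cdf(hist)
        assert np.all(cdf[:100] == 0)
        assert np.allclose(cdf[100:], 1.0)

    def test_two_equal_levels(self):
        hist = np.zeros(256)
        hist[[50, 200]] = 10
        cdf = compute_weighted_cdf(hist)
        assert cdf[50] == pytest.approx(0.5)
        assert cdf[200] == pytest.approx(1.0)
        assert np.all(np.diff(cdf) >= 0)

    def test_flat_histogram_falls_back_to_plain_cdf(self):
        cdf = compute_weighted_cdf(np.ones(256))
        assert np.allclose(cdf, np.arange(1, 257) / 256)

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(ValueError):
            compute_weighted_cdf(np.zeros(256))


class TestGcadw:
    def test_constant_image_unchanged(self):
        img = np.full((8, 8), 100 / 255)
        assert np.allclose(gcadw_enhance(img), img)

    def test_top_level_is_fixed_point(self, rng):
        img = np.clip(rng.random((16, 16)), 0, 1)
        img[0, 0] = 1.0
        out = gcadw_enhance(img)
        assert out[0, 0] == pytest.approx(1.0)

    def test_mapping_is_monotone_in_level(self, rng):
        img = rng.random((32, 32))
        out = gcadw_enhance(img)
        lv_in = np.floor(img * 255 + 0.5)
        order = np.argsort(lv_in.ravel())
        assert np.all(np.diff(out.ravel()[order]) >= -1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scalar_oracle(self, seed):
        rng = np.random.default_rng(seed)
        levels = rng.choice([40, 180], size=(8, 8))
        img = levels / 255.0
        out = gcadw_enhance(img, GcadwConfig(a=0.5))
        expected = gcadw_map_oracle(levels.tolist(), a=0.5) / 255.0
        assert np.allclose(out, expected, atol=1e-12)

    def test_oracle_agreement_on_multilevel_image(self):
        rng = np.random.default_rng(3)
        levels = rng.integers(0, 256, size=(8, 8))
        out = gcadw_enhance(levels / 255.0)
        expected = gcadw_map_oracle(levels.tolist(), a=0.5) / 255.0
        assert np.allclose(out, expected, atol=1e-12)


class TestHomomorphic:
    def test_transfer_function_anchors(self):
        cfg = HomomorphicConfig()
        assert homomorphic_transfer(np.array(0.0), cfg, p0=10.0) == pytest.approx(0.6)
        assert homomorphic_transfer(np.array(1e6), cfg, p0=10.0) == pytest.approx(0.8)

    def test_transfer_function_monotone(self):
        cfg = HomomorphicConfig()
        p = np.linspace(0, 100, 500)
        h = homomorphic_transfer(p, cfg, p0=10.0)
        assert np.all(np.diff(h) >= 0)

    def test_constant_image_stays_constant(self):
        out = homomorphic_enhance(np.full((32, 32), 0.4))
        assert np.allclose(out, out[0, 0])

    def test_gain_ordering_enforced(self):
        with pytest.raises(ValueError):
            HomomorphicConfig(gamma_high=0.5, gamma_low=0.6)

    def test_output_in_unit_range(self, small_phantom):
        img, _, _ = small_phantom
        out = homomorphic_enhance(img.green)
        assert out.min() >= 0 and out.max() <= 1
        assert out.shape == img.green.shape


class TestNeighborhoodMean:
    def test_constant(self):
        assert np.allclose(neighborhood_mean(np.full((5, 5), 0.3)), 0.3)

    def test_center_of_1_to_9(self):
        img = np.arange(1, 10).reshape(3, 3) / 10.0
        assert neighborhood_mean(img)[1, 1] == pytest.approx(0.5)

    def test_replicate_padding_at_corner(self):
        img = np.array([[0.0, 0.0], [1.0, 1.0]])
        # top-left 3x3 window replicates: six 0s and three 1s
        assert neighborhood_mean(img, 3)[0, 0] == pytest.approx(1 / 3)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            neighborhood_mean(np.zeros((4, 4)), 4)


class TestJeh:
    def test_worked_example_level(self):
        # CDF 11, CDF_min 1, 6x6 image: trunc(10/35 * 255) = 72
        assert jeh_equalized_level(11, 1, 36) == 72

    def test_constant_image_maps_to_zero(self):
        out = jeh_equalize(np.full((6, 6), 0.7))
        assert np.array_equal(out, np.zeros((6, 6)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(6, 6)) / 255.0
        assert np.array_equal(jeh_equalize(img), jeh_oracle(img))

    def test_equal_pairs_get_equal_outputs(self, rng):
        img = rng.integers(0, 8, size=(12, 12)) / 255.0  # few levels -> many ties
        out = jeh_equalize(img)
        ws = jeh_workspace(img)
        f = np.floor(img * 255 + 0.5).astype(int)
        g = np.floor(np.clip(neighborhood_mean(img), 0, 1) * 255 + 0.5).astype(int)
        seen = {}
        for pair, val in zip(zip(f.ravel(), g.ravel()), out.ravel()):
            assert seen.setdefault(pair, val) == val
        assert ws.joint_histogram.sum() == img.size

    def test_workspace_invariants(self, rng):
        img = rng.random((10, 10))
        ws = jeh_workspace(img)
        assert ws.cdf_min >= 1
        assert np.all(np.diff(ws.cdf2d, axis=0) >= 0)
        assert np.all(np.diff(ws.cdf2d, axis=1) >= 0)
        assert ws.cdf2d[-1, -1] == img.size


class TestUnsharp:
    def test_zero_gain_is_identity(self, rng):
        img = rng.random((16, 16))
        cfg = UnsharpConfig(gain_k=0.0, allow_gain_outside_range=True)
        assert np.allclose(unsharp_enhance(img, cfg), img)

    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 0.42)
        assert np.allclose(unsharp_enhance(img), img)

    def test_gain_range_enforced(self):
        with pytest.raises(ValueError):
            UnsharpConfig(gain_k=0.9)

    def test_step_edge_overshoot(self):
        # sharpening a step produces overshoot above the high plateau and
        # undershoot below the low one
        img = np.full((32, 32), 0.3)
        img[:, 16:] = 0.6
        out = unsharp_enhance(img, UnsharpConfig(gain_k=0.7))
        assert out[:, 16:20].max() > 0.6
        assert out[:, 12:16].min() < 0.3

    def test_shape_and_range(self, small_phantom):
        img, _, _ = small_phantom
        out = unsharp_enhance(img.green)
        assert out.shape == img.green.shape
        assert out.min() >= 0 and out.max() <= 1
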