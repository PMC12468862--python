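import numpy as np
import pytest

from pleurakit import (AHEParams, EnhanceConfig, ParameterError, PhantomConfig,
                       SobelConfig, adaptive_equalize, canny, clahe, enhance,
                       generate_phantom, histogram_stretch, log_transform,
                       sharpen, sobel_edges, sobel_fields, sobel_gradient)
from pleurakit.enhancement import SOBEL_X, SOBEL_Y
from oracles import convolve_replicate


class TestHistogramStretch:
    def test_three_level_toy(self):
        img = np.full((8, 8), 0.45)
        img[0, 0], img[7, 7] = 0.2, 0.7
        out = histogram_stretch(img)
        assert out[0, 0] == 0.0 and out[7, 7] == 1.0
        assert np.isclose(out[3, 3], 0.5)

    def test_full_range_image_unchanged(self, rng):
        img = rng.uniform(size=(16, 16))
        img[0, 0], img[1, 1] = 0.0, 1.0
        assert np.allclose(histogram_stretch(img), img)

    def test_idempotent_after_first_application(self, rng):
        img = rng.uniform(0.3, 0.6, size=(16, 16))
        once = histogram_stretch(img)
        assert np.allclose(histogram_stretch(once), once)

    def test_attains_bounds_and_preserves_order(self, rng):
        img = rng.uniform(0.2, 0.8, size=(16, 16))
        out = histogram_stretch(img)
        assert out.min() == 0.0 and out.max() == 1.0
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in)
        assert (np.diff(flat_out[order]) >= -1e-12).all()

    def test_constant_image_warns_and_passes_through(self):
        img = np.full((8, 8), 0.4)
        with pytest.warns(RuntimeWarning):
            out = histogram_stretch(img)
        assert np.array_equal(out, img)


class TestLogTransform:
    def test_zero_and_endpoints(self):
        assert not log_transform(np.zeros((8, 8))).any()
        img = np.zeros((8, 8))
        img[0, 0] = 1.0
        out = log_transform(img, scale=1.0)
        assert out[0, 0] == 1.0 and out[1, 1] == 0.0

    def test_monotone(self, rng):
        img = np.tile(np.linspace(0, 1, 16), (8, 1))
        out = log_transform(img, 5.0)
        assert (np.diff(out[0]) > 0).all()

    def test_scale_domain(self):
        with pytest.raises(ParameterError):
            log_transform(np.zeros((8, 8)), scale=0.0)


class TestClahe:
    def test_constant(self):
        assert np.ptp(clahe(np.full((64, 64), 0.5), AHEParams(2, 2, 0.5))) == 0.0

    def test_requires_clip_limit(self):
        with pytest.raises(ParameterError):
            clahe(np.zeros((64, 64)), AHEParams(2, 2, clip_limit=None))

    def test_clip_limit_one_equals_unclipped(self, rng):
        img = rng.uniform(size=(64, 64))
        assert np.array_equal(clahe(img, AHEParams(1, 1, 1.0)),
                              adaptive_equalize(img, AHEParams(1, 1, None)))

    def test_clipping_limits_contrast_amplification(self, rng):
        # near-constant noisy image: unclipped AHE flattens the noise
        # histogram toward uniform, histogram clipping must damp that
        img = np.clip(0.5 + rng.normal(0, 0.01, size=(64, 64)), 0, 1)
        unclipped = adaptive_equalize(img, AHEParams(4, 4))
        clipped = clahe(img, AHEParams(4, 4, clip_limit=0.005))
        assert clipped.std() < unclipped.std()


class TestSobel:
    def test_kernels_are_the_printed_matrices(self):
        assert np.array_equal(SOBEL_X, [[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]])
        assert np.array_equal(SOBEL_Y, [[-1, -2, -1], [0, 0, 0], [1, 2, 1]])

    def test_constant_image_zero_gradient(self):
        _, _, mag, _ = sobel_fields(np.full((16, 16), 0.7))
        assert np.allclose(mag, 0.0)

    def test_vertical_step_edge(self):
        img = np.zeros((9, 10))
        img[:, 5:] = 1.0
        gx, gy, mag, theta = sobel_fields(img)
        r, c = 4, 5  # interior pixel on the edge
        assert gy[r, c] == 0.0
        assert np.isclose(mag[r, c], abs(gx[r, c]))
        assert theta[r, c] == 0.0

    def test_matches_loop_convolution_oracle(self, rng):
        img = rng.uniform(size=(10, 12))
        gx, gy, _, _ = sobel_fields(img)
        assert np.allclose(gx, convolve_replicate(img, SOBEL_X))
        assert np.allclose(gy, convolve_replicate(img, SOBEL_Y))

    def test_horizontal_ramp_constant_gx(self):
        w = 12
        img = np.tile(np.arange(w) / w, (8, 1))
        gx, gy, _, _ = sobel_fields(img)
        interior = gx[1:-1, 1:-1]
        assert np.allclose(interior, interior[0, 0])
        assert np.allclose(gy[1:-1, 1:-1], 0.0)

    def test_gradient_chain_constant_image(self):
        out = sobel_gradient(np.full((16, 16), 0.3))
        assert np.ptp(out) == 0.0

    def test_small_image_rejected(self):
        from pleurakit.errors import PleuraKitError
        with pytest.raises(PleuraKitError):
            sobel_fields(np.ones((2, 8)) * 0.5)

    def test_plain_sobel_is_binary_map(self, rng):
        out = sobel_edges(rng.uniform(size=(16, 16)), threshold=0.5)
        assert set(np.unique(out)) <= {0.0, 1.0}


class TestSharpen:
    def test_zero_amount_is_identity(self, rng):
        img = rng.uniform(size=(12, 12))
        assert np.array_equal(sharpen(img, 0.0), img)

    def test_constant_unchanged(self):
        img = np.full((12, 12), 0.6)
        assert np.allclose(sharpen(img, 3.0), img)

    def test_step_overshoot(self):
        img = np.zeros((12, 12))
        img[:, 6:] = 0.5
        out = sharpen(img, 2.0)
        assert out[:, 6:8].max() > 0.5  # bright-side overshoot next to edge


class TestCanny:
    def test_constant_image_empty(self):
        assert not canny(np.full((16, 16), 0.5)).any()

    def test_step_edge_single_pixel_line(self):
        # a mid-level column breaks the discrete two-pixel gradient tie,
        # so non-maximum suppression keeps exactly one pixel per row
        img = np.zeros((16, 16))
        img[:, 7] = 0.5
        img[:, 8:] = 1.0
        out = canny(img)
        rows = out[4:12]
        assert (rows.sum(axis=1) == 1).all()
        assert rows[:, 6:9].sum() == rows.sum()  # line hugs the step

    def test_threshold_order_enforced(self):
        with pytest.raises(ParameterError):
            canny(np.zeros((16, 16)), low=0.5, high=0.2)


class TestEnhance:
    def test_identity_config(self, rng):
        img = rng.uniform(size=(16, 16))
        out = enhance(img, EnhanceConfig("none", "none"))
        assert np.array_equal(out, img)

    def test_stretch_only_matches_toy(self):
        img = np.full((8, 8), 0.45)
        img[0, 0], img[7, 7] = 0.2, 0.7
        out = enhance(img, EnhanceConfig("stretch", "none"))
        assert out[0, 0] == 0.0 and np.isclose(out[3, 3], 0.5) and out[7, 7] == 1.0

    @pytest.mark.parametrize("contrast", ["none", "log", "stretch"])
    @pytest.mark.parametrize("edge", ["none", "sobel", "sobel_gradient",
                                      "sharpen", "canny"])
    def test_all_methods_stay_in_unit_interval(self, contrast, edge, rng):
        img = rng.uniform(size=(32, 32))
        out = enhance(img, EnhanceConfig(contrast, edge))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_stage_errors_are_tagged(self):
        with pytest.raises(ParameterError, match="edge stage"):
            enhance(np.random.default_rng(0).uniform(size=(16, 16)),
                    EnhanceConfig("none", "canny", canny_low=0.9, canny_high=0.1))

    def test_junction_gradient_sharper_without_effusion(self, phantom_pair):
        """The costophrenic angle of a normal phantom has a steeper local
        gradient than the blunted, fluid-filled angle."""
        normal, effusion = phantom_pair
        means = []
        for s in (normal, effusion):
            jr, jc = s.truth.junctions["right"]
            _, _, mag, _ = sobel_fields(s.image, 1.0)
            means.append(mag[jr - 6:jr + 2, jc - 8:jc + 8].mean())
        assert means[0] > means[1]
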