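"""The five-step scoring protocol: grayscale, inversion, ROI statistics, TBR."""

import numpy as np
import pytest

from ihcscore import (
    GrayscaleRaster,
    RGBImage,
    ROIStats,
    compute_tbr,
    gradient_map,
    invert,
    measure_roi,
    score_slide,
    to_grayscale,
)
from ihcscore.errors import (
    EmptyROIError,
    InvalidParameterError,
    StateError,
    UndefinedTBRError,
)
from ihcscore.scoring import LUMINANCE_WEIGHTS
from ihcscore.synthetic import (
    PhantomSpec,
    default_geometry,
    forward_model,
    inverted_gray_of_density,
)


def _flat_image(rgb, shape=(2, 2)):
    return RGBImage(np.tile(np.asarray(rgb, float), (*shape, 1)), bit_depth="continuous")


class TestGrayscale:
    def test_equal_weights_are_channel_mean(self):
        g = to_grayscale(_flat_image([30, 60, 90]))
        assert np.allclose(g.values, 60.0)

    def test_white_stays_white(self):
        g = to_grayscale(_flat_image([255, 255, 255]))
        assert np.allclose(g.values, 255.0)

    def test_luminance_weights(self):
        g = to_grayscale(_flat_image([30, 60, 90]), weights=LUMINANCE_WEIGHTS)
        assert np.allclose(g.values, 54.45)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            to_grayscale(_flat_image([1, 2, 3]), weights=(0.5, 0.5, 0.5))


class TestInvert:
    def test_endpoints_flip(self):
        g = GrayscaleRaster(np.array([[0.0, 255.0]]))
        inv = invert(g)
        assert inv.inverted
        assert np.allclose(inv.values, [[255.0, 0.0]])

    def test_mean_is_complemented(self):
        rng = np.random.default_rng(3)
        g = GrayscaleRaster(rng.uniform(0, 255, (5, 5)))
        assert np.isclose(invert(g).values.mean(), 255.0 - g.values.mean())

    def test_double_inversion_rejected(self):
        with pytest.raises(StateError):
            invert(invert(GrayscaleRaster(np.zeros((1, 1)))))


class TestMeasureRoi:
    def test_constant_region(self):
        g = GrayscaleRaster(np.full((3, 3), 100.0), inverted=True)
        stats = measure_roi(g, np.ones((3, 3), bool))
        assert stats.mean == 100.0 and stats.sd == 0.0 and stats.n_pixels == 9

    def test_two_value_sample_sd(self):
        g = GrayscaleRaster(np.array([[10.0, 20.0]]), inverted=True)
        stats = measure_roi(g, np.ones((1, 2), bool))
        assert np.isclose(stats.mean, 15.0)
        assert np.isclose(stats.sd, np.sqrt(50.0))  # n-1 denominator

    def test_full_mask_matches_global_stats(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 255, (8, 8))
        g = GrayscaleRaster(vals, inverted=True)
        stats = measure_roi(g, np.ones((8, 8), bool))
        assert np.isclose(stats.mean, vals.mean())
        assert np.isclose(stats.sd, vals.std(ddof=1))

    def test_requires_inverted_raster(self):
        with pytest.raises(StateError):
            measure_roi(GrayscaleRaster(np.zeros((2, 2))), np.ones((2, 2), bool))

    def test_empty_mask_rejected(self):
        g = GrayscaleRaster(np.zeros((2, 2)), inverted=True)
        with pytest.raises(EmptyROIError):
            measure_roi(g, np.zeros((2, 2), bool))

    def test_single_pixel_warns_and_reports_zero_sd(self):
        g = GrayscaleRaster(np.array([[42.0, 0.0]]), inverted=True)
        mask = np.array([[True, False]])
        with pytest.warns(UserWarning, match="single pixel"):
            stats = measure_roi(g, mask)
        assert stats.sd == 0.0 and stats.mean == 42.0


class TestComputeTbr:
    @pytest.mark.parametrize(
        "tumor_mean,bg_mean,expected",
        [(50.0, 50.0, 1.0), (90.0, 45.0, 2.0), (81.0, 81.0 / 3.1, 3.1)],
    )
    def test_ratio(self, tumor_mean, bg_mean, expected):
        t = ROIStats(mean=tumor_mean, sd=1.0, n_pixels=10)
        b = ROIStats(mean=bg_mean, sd=1.0, n_pixels=10)
        assert np.isclose(compute_tbr(t, b), expected)

    def test_below_unity_is_legal(self):
        t = ROIStats(mean=10.0, sd=1.0, n_pixels=10)
        b = ROIStats(mean=20.0, sd=1.0, n_pixels=10)
        assert compute_tbr(t, b) == 0.5

    def test_zero_background_is_undefined(self):
        t = ROIStats(mean=10.0, sd=1.0, n_pixels=10)
        b = ROIStats(mean=0.0, sd=0.0, n_pixels=10)
        with pytest.raises(UndefinedTBRError):
            compute_tbr(t, b)


def _noiseless_spec(d_tumor, d_bg, size=96, hematoxylin=0.3, seed=0):
    tumor, sectors = default_geometry(size, size)
    return PhantomSpec(
        height=size,
        width=size,
        tumor_polygon=tumor,
        background_polygons=sectors,
        dab_density_tumor=d_tumor,
        dab_density_background=d_bg,
        hematoxylin_density=hematoxylin,
        pixel_noise_sd=0.0,
        vacuole_fraction=0.0,
        seed=seed,
    )


class TestScoreSlide:
    def test_equal_densities_give_unit_tbr(self, model):
        slide = forward_model(_noiseless_spec(0.4, 0.4), model)
        score = score_slide(slide.image, slide.roiset, model)
        assert abs(score.tbr - 1.0) < 0.02

    def test_noiseless_tbr_matches_closed_form(self, model):
        d_t, d_b = 0.5, 0.15
        slide = forward_model(_noiseless_spec(d_t, d_b, size=160), model)
        score = score_slide(slide.image, slide.roiset, model)
        expected = inverted_gray_of_density(d_t, model) / inverted_gray_of_density(d_b, model)
        # one 8-bit quantization step of slack on each regional mean
        f_b = inverted_gray_of_density(d_b, model)
        tol = (1.0 + expected) / f_b
        assert abs(score.tbr - expected) <= tol

    def test_noiseless_mean_matches_closed_form_within_quantization(self, model):
        d_t = 0.45
        slide = forward_model(_noiseless_spec(d_t, 0.1, size=160), model)
        score = score_slide(slide.image, slide.roiset, model)
        assert abs(score.tumor.mean - inverted_gray_of_density(d_t, model)) <= 1.0

    def test_hematoxylin_only_crosstalk_bounded(self, model):
        from ihcscore import deconvolve, render_stain, rgb_to_od

        slide = forward_model(_noiseless_spec(0.0, 0.0, hematoxylin=0.6), model)
        dab = deconvolve(rgb_to_od(slide.image), model).channel("dab")
        rendered = render_stain(dab, model.stain_vector("dab"))
        inv = invert(to_grayscale(rendered))
        for label in ("tumor", "background"):
            assert measure_roi(inv, slide.roiset.mask(label)).mean <= 2.0

    def test_hematoxylin_variation_barely_moves_dab_channel(self, model):
        means = []
        for h in (0.2, 0.5):
            slide = forward_model(_noiseless_spec(0.3, 0.3, hematoxylin=h), model)
            means.append(score_slide(slide.image, slide.roiset, model).tumor.mean)
        assert abs(means[1] - means[0]) <= 2.0

    def test_tumor_mean_monotone_in_density(self, model):
        means = []
        for d in (0.1, 0.3, 0.5, 0.8):
            spec = _noiseless_spec(d, 0.1, seed=9)
            spec = type(spec)(**{**spec.__dict__, "pixel_noise_sd": 0.03})
            slide = forward_model(spec, model)
            means.append(score_slide(slide.image, slide.roiset, model).tumor.mean)
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_label_swap_inverts_tbr(self, model):
        slide = forward_model(_noiseless_spec(0.5, 0.15), model)
        score = score_slide(slide.image, slide.roiset, model)
        swapped = score_slide(slide.image, slide.roiset.swapped_labels(), model)
        assert abs(swapped.tbr - 1.0 / score.tbr) < 1e-9

    def test_errors_tagged_with_step(self, model):
        slide = forward_model(_noiseless_spec(0.5, 0.15), model)
        with pytest.raises(InvalidParameterError, match="step 3"):
            score_slide(slide.image, slide.roiset, model, grayscale_weights=(1, 1, 1))


class TestGradientMap:
    def test_endpoints_map_to_colormap_ends(self):
        import matplotlib

        arr = np.array([[0.0, 128.0], [64.0, 255.0]])
        gm = gradient_map(arr, colormap="viridis")
        cmap = matplotlib.colormaps["viridis"]
        lo = np.rint(np.asarray(cmap(0.0))[:3] * 255)
        hi = np.rint(np.asarray(cmap(1.0))[:3] * 255)
        assert np.allclose(gm.image.pixels[0, 0], lo)
        assert np.allclose(gm.image.pixels[1, 1], hi)
        assert (gm.vmin, gm.vmax) == (0.0, 255.0)

    def test_monotone_rows_give_monotone_luminance(self):
        arr = np.tile(np.linspace(0, 100, 32), (2, 1))
        gm = gradient_map(arr, colormap="gray")
        lum = gm.image.pixels[0].mean(axis=-1)
        assert np.all(np.diff(lum) >= 0)

    def test_constant_raster_warns_and_uses_midpoint(self):
        import matplotlib

        with pytest.warns(UserWarning, match="constant"):
            gm = gradient_map(np.full((2, 2), 7.0))
        mid = np.rint(np.asarray(matplotlib.colormaps["viridis"](0.5))[:3] * 255)
        assert np.allclose(gm.image.pixels[0, 0], mid)
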