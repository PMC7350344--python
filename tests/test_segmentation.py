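"""Gaussian-mixture pixel classification and mask cleaning."""

import numpy as np
import pytest

from rootmorph import segmentation as seg
from rootmorph.imaging import BinaryMask, RasterImage


def _image_from(values):
    return RasterImage(np.asarray(values, dtype=float), dpi=450)


class TestSamplePixels:
    def test_small_image_returns_all_pixels(self):
        im = _image_from(np.random.default_rng(0).random((10, 10)))
        assert seg.sample_pixels(im, max_samples=1000, seed=0).shape == (100, 1)

    def test_deterministic_given_seed(self):
        im = _image_from(np.random.default_rng(1).random((400, 500)))
        a = seg.sample_pixels(im, max_samples=1000, seed=42)
        b = seg.sample_pixels(im, max_samples=1000, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_subsample_count_and_uniqueness(self):
        px = np.linspace(0, 1, 10**6).reshape(1000, 1000)
        im = _image_from(px)
        s = seg.sample_pixels(im, max_samples=10**5, seed=3)
        assert s.shape == (10**5, 1)
        assert np.unique(s).size == 10**5  # all intensities distinct here


class TestFitMixture:
    def test_two_component_recovery(self):
        rng = np.random.default_rng(10)
        x = np.concatenate(
            [rng.normal(0.2, 0.05, 5000), rng.normal(0.8, 0.05, 5000)]
        )[:, None]
        model = seg.fit_mixture(x, K=2, seed=0)
        means = np.sort(model.means.ravel())
        assert means == pytest.approx([0.2, 0.8], abs=0.01)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_log_likelihood_monotone_and_matches_direct_eval(self):
        rng = np.random.default_rng(11)
        x = np.concatenate(
            [rng.normal(0.3, 0.04, 2000), rng.normal(0.7, 0.06, 3000)]
        )[:, None]
        model = seg.fit_mixture(x, K=2, seed=5)
        trace = np.array(model.ll_trace)
        assert (np.diff(trace) >= -1e-7 * np.abs(trace[:-1])).all()
        # final trace entry equals an independent evaluation of the mixture ll
        from scipy.stats import norm

        dens = np.zeros(x.shape[0])
        for w, m, v in zip(model.weights, model.means.ravel(), model.variances.ravel()):
            dens += w * norm.pdf(x.ravel(), m, np.sqrt(v))
        assert np.log(dens).sum() == pytest.approx(model.log_likelihood, rel=1e-9)

    def test_degenerate_constant_input_k1(self):
        x = np.full((500, 1), 0.37)
        model = seg.fit_mixture(x, K=1, seed=0)
        assert model.means.ravel()[0] == pytest.approx(0.37)
        assert model.variances.ravel()[0] == pytest.approx(seg.VARIANCE_FLOOR)

    def test_degenerate_constant_input_k3_flags_not_crashes(self):
        x = np.full((500, 1), 0.37)
        model = seg.fit_mixture(x, K=3, seed=0)
        assert model.degenerate
        assert model.weights.max() == pytest.approx(1.0)
        assert (model.variances >= seg.VARIANCE_FLOOR).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            seg.fit_mixture(np.zeros((25, 1)), K=3)

    def test_agrees_with_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(12)
        x = np.concatenate(
            [rng.normal(0.25, 0.05, 4000), rng.normal(0.75, 0.05, 4000)]
        )[:, None]
        ours = np.sort(seg.fit_mixture(x, K=2, seed=0).means.ravel())
        ref = sklearn.GaussianMixture(2, random_state=0).fit(x)
        theirs = np.sort(ref.means_.ravel())
        np.testing.assert_allclose(ours, theirs, atol=0.01)


class TestPosteriors:
    @pytest.fixture()
    def model(self):
        return seg.MixtureModel(
            weights=np.array([0.5, 0.5]),
            means=np.array([[0.2], [0.8]]),
            variances=np.array([[0.0025], [0.0025]]),
        )

    def test_rows_sum_to_one(self, model):
        im = _image_from(np.random.default_rng(13).random((30, 30)))
        post = seg.posterior_map(im, model)
        np.testing.assert_allclose(post.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_component_mean_pixel_is_confident(self, model):
        post = seg.posterior_map(_image_from([[0.2]]), model)
        assert post.probs[0, 0, 0] > 0.999

    def test_symmetric_midpoint_is_half(self, model):
        post = seg.posterior_map(_image_from([[0.5]]), model)
        assert post.probs[0, 0] == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_matches_direct_density_formula(self, model):
        from scipy.stats import norm

        vals = np.array([[0.1, 0.35, 0.62], [0.5, 0.9, 0.77]])
        post = seg.posterior_map(_image_from(vals), model)
        d0 = 0.5 * norm.pdf(vals, 0.2, 0.05)
        d1 = 0.5 * norm.pdf(vals, 0.8, 0.05)
        np.testing.assert_allclose(post.probs[..., 0], d0 / (d0 + d1), rtol=1e-9)

    def test_classification_tie_included(self, model):
        post = seg.posterior_map(_image_from([[0.5, 0.9]]), model)
        mask = seg.classify_root_pixels(post, {0}, min_posterior=0.5)
        assert mask.pixels[0, 0]  # exactly 0.5 is included
        assert not mask.pixels[0, 1]

    def test_unknown_component_rejected(self, model):
        post = seg.posterior_map(_image_from([[0.5]]), model)
        with pytest.raises(ValueError):
            seg.classify_root_pixels(post, {7})

    def test_no_root_component_on_pure_noise(self):
        rng = np.random.default_rng(14)
        x = rng.normal(0.9, 0.02, (3000, 1)).clip(0, 1)
        model = seg.fit_mixture(x, K=3, seed=0)
        assert seg.select_root_components(model, 1) == set()

    def test_root_component_selected_when_separated(self):
        rng = np.random.default_rng(15)
        x = np.concatenate(
            [rng.normal(0.9, 0.02, 8000), rng.normal(0.2, 0.02, 1500)]
        ).clip(0, 1)[:, None]
        model = seg.fit_mixture(x, K=2, seed=0)
        sel = seg.select_root_components(model, 1)
        assert sel == seg.darkest_components(model, 1)


class TestCleanMask:
    def test_empty_mask_unchanged(self):
        m = BinaryMask(np.zeros((20, 20), bool), dpi=450)
        assert seg.clean_mask(m).pixels.sum() == 0

    def test_small_speck_removed(self):
        px = np.zeros((20, 20), bool)
        px[5, 5:8] = True  # 3-px speck
        out = seg.clean_mask(BinaryMask(px, dpi=450), min_speck_px=10, fill_hole_px=0)
        assert out.pixels.sum() == 0

    def test_small_hole_filled(self):
        from skimage.draw import disk

        px = np.zeros((40, 40), bool)
        rr, cc = disk((20, 20), 10)
        px[rr, cc] = True
        hole = np.zeros_like(px)
        rr, cc = disk((20, 20), 1.4)
        hole[rr, cc] = True
        annulus = px & ~hole
        out = seg.clean_mask(
            BinaryMask(annulus, dpi=450), min_speck_px=0, fill_hole_px=10
        )
        np.testing.assert_array_equal(out.pixels, px)

    def test_large_hole_kept(self):
        px = np.ones((30, 30), bool)
        px[5:25, 5:25] = False  # 400-px hole
        out = seg.clean_mask(BinaryMask(px, dpi=450), min_speck_px=0, fill_hole_px=100)
        assert not out.pixels[15, 15]


class TestRemoveDirt:
    def test_elongated_bar_kept(self):
        px = np.zeros((40, 250), bool)
        px[15:24, 20:220] = True  # 200x9 bar, ellipse elongation ~20
        out, stats = seg.remove_dirt(BinaryMask(px, dpi=450))
        assert out.pixels.sum() == px.sum()
        assert stats[0].elongation > 3
        assert not stats[0].removed

    def test_compact_disc_removed(self):
        from skimage.draw import disk

        px = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 15)
        px[rr, cc] = True
        out, stats = seg.remove_dirt(BinaryMask(px, dpi=450))
        assert out.pixels.sum() == 0
        assert stats[0].elongation < 1.2 and stats[0].removed

    def test_curved_root_kept_by_skeleton_aspect(self):
        # a C-shaped stroke: second-moment ellipse is roundish, but the
        # skeleton is long relative to the width
        rows, cols = np.mgrid[0:120, 0:120]
        r = np.hypot(rows - 60, cols - 60)
        px = (np.abs(r - 40) <= 4) & (cols < 72)
        out, stats = seg.remove_dirt(BinaryMask(px, dpi=450))
        assert stats[0].skeleton_aspect > 3
        assert out.pixels.sum() == px.sum()

    def test_output_subset_of_input_and_empty_ok(self):
        out, stats = seg.remove_dirt(BinaryMask(np.zeros((10, 10), bool), dpi=450))
        assert out.pixels.sum() == 0 and stats == []
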