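"""Pixel/texture statistics and the twofold cross-validation harness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from glossbench import linear_baselines as lb


class TestPixelStats:
    def test_length_eight(self):
        img = np.random.default_rng(0).random((16, 16, 3))
        assert lb.pixel_stats(img).shape == (8,)

    def test_constant_gray_degenerates(self):
        img = np.full((8, 8, 3), 0.5)
        assert np.allclose(lb.pixel_stats(img), [0.5, 0, 0, 0, 0, 0, 0, 0])

    def test_two_valued_luminance_moments_match_bruteforce(self):
        """50/50 black/white pixels: moments of the multiset {0,1}."""
        img = np.zeros((4, 4, 3))
        img[:2] = 1.0
        m, v, sk, ku = lb.pixel_stats(img)[:4]
        pixels = np.array([0.0] * 8 + [1.0] * 8)
        assert m == pytest.approx(pixels.mean())
        assert v == pytest.approx(pixels.var())
        assert v == pytest.approx(0.25)
        assert sk == pytest.approx(sstats.skew(pixels)) == pytest.approx(0.0)
        assert ku == pytest.approx(sstats.kurtosis(pixels, fisher=False)) == pytest.approx(1.0)

    def test_moments_match_scipy_on_random_image(self):
        rng = np.random.default_rng(1)
        img = rng.random((12, 12, 3))
        from glossbench.observer_sim import luminance

        lum = luminance(img).ravel()
        got = lb.pixel_stats(img)[:4]
        want = [lum.mean(), lum.var(), sstats.skew(lum), sstats.kurtosis(lum, fisher=False)]
        assert np.allclose(got, want)


class TestTextureStats:
    def test_deterministic_and_fixed_length(self):
        rng = np.random.default_rng(2)
        img = rng.random((64, 64, 3))
        cfg = lb.TextureConfig()
        a, b = lb.texture_stats(img, cfg), lb.texture_stats(img, cfg)
        assert np.array_equal(a, b)
        assert a.shape == (cfg.vector_length(),)
        assert len(lb.texture_stat_labels(cfg)) == cfg.vector_length()

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            lb.texture_stats(np.zeros((16, 16, 3)), lb.TextureConfig(scales=3))

    def test_oriented_grating_dominates_its_subband(self):
        """A horizontal-frequency grating concentrates energy in one
        orientation band >10x more than matched white noise does."""
        n = 64
        x = np.arange(n)
        grating = np.tile(0.5 + 0.5 * np.sin(2 * np.pi * x * 8 / n), (n, 1))
        grating = np.repeat(grating[..., None], 3, axis=2)
        rng = np.random.default_rng(3)
        noise = rng.normal(0.5, grating.std(), (n, n, 3))
        cfg = lb.TextureConfig()
        labels = lb.texture_stat_labels(cfg)
        sg = pd.Series(lb.texture_stats(grating, cfg), index=labels)
        sn = pd.Series(lb.texture_stats(noise, cfg), index=labels)
        # vertical-edge band at the grating frequency's scale
        key = "ch0_s1_v_var"
        assert sg[key] > 10 * sn[key]

    def test_pixel_shuffle_keeps_marginals_changes_autocorr(self):
        rng = np.random.default_rng(4)
        from glossbench import stimulus_synth as ss

        c = ss.generate_scene_components(5, size=64)
        img = ss.compose_image(c, ss.GlossParams(0.98))
        perm = rng.permutation(img.reshape(-1, 3))
        shuffled = perm.reshape(img.shape)
        cfg = lb.TextureConfig()
        labels = lb.texture_stat_labels(cfg)
        a = pd.Series(lb.texture_stats(img, cfg), index=labels)
        b = pd.Series(lb.texture_stats(shuffled, cfg), index=labels)
        marg = [l for l in labels if l.startswith("ch0_") and l.count("_") == 1]
        assert np.allclose(a[marg], b[marg], rtol=1e-8)
        acorr = [l for l in labels if "acorr" in l]
        assert np.abs(a[acorr] - b[acorr]).max() > 0.1


class TestPcaReduce:
    def test_rank_one_needs_one_component(self):
        rng = np.random.default_rng(5)
        X = np.outer(rng.random(30), rng.random(6))
        proj, Z = lb.pca_reduce(X, 0.99)
        assert Z.shape[1] == 1

    def test_threshold_one_keeps_rank(self):
        rng = np.random.default_rng(6)
        X = rng.random((20, 5)) @ np.eye(5)
        proj, Z = lb.pca_reduce(X, 1.0)
        assert Z.shape[1] == np.linalg.matrix_rank(X - X.mean(0))

    def test_isotropic_gaussian_needs_most_components(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((2000, 50))
        _, Z = lb.pca_reduce(X, 0.99)
        assert Z.shape[1] >= 45  # ~0.99 * d up to sampling error

    def test_reconstruction_error_bounded_by_threshold(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((100, 20)) @ rng.standard_normal((20, 20))
        thr = 0.95
        proj, Z = lb.pca_reduce(X, thr)
        Xhat = proj.inverse_transform(Z)
        rel = np.linalg.norm(X - Xhat) ** 2 / np.linalg.norm(X - X.mean(0)) ** 2
        assert rel <= (1 - thr) + 1e-9

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            lb.pca_reduce(np.eye(4), 1.5)


class TestTwofoldCV:
    def _toy(self, n_scenes=20, separable=True, seed=0):
        rng = np.random.default_rng(seed)
        scene_ids = np.repeat([f"s{i}" for i in range(n_scenes)], 2)
        labels = np.tile([0, 1], n_scenes)
        X = rng.standard_normal((2 * n_scenes, 3))
        if separable:
            X[:, 0] += labels * 10.0
        return X, labels, scene_ids

    def test_each_image_gets_n_repeats_predictions(self):
        X, y, s = self._toy()
        table = lb.twofold_cv(X, y, s, model="max-margin", n_repeats=10, seed=1)
        counts = table.groupby("image_index").size()
        assert (counts == 10).all()

    def test_separable_features_reach_full_accuracy(self):
        X, y, s = self._toy(separable=True)
        table = lb.twofold_cv(X, y, s, model="max-margin", n_repeats=3, seed=1)
        assert lb.cv_accuracy(table, y) == 1.0

    def test_shuffled_labels_fall_to_chance(self):
        rng = np.random.default_rng(9)
        X, y, s = self._toy(n_scenes=100, separable=True, seed=2)
        # randomly flip each scene's label pair: features stay structured
        # but carry no information about the reassigned labels
        flips = rng.integers(0, 2, 100).astype(bool)
        y = np.where(np.repeat(flips, 2), 1 - y, y)
        table = lb.twofold_cv(X, y, s, model="logistic", n_repeats=4, seed=3)
        acc = lb.cv_accuracy(table, y)
        assert abs(acc - 0.5) < 0.15  # ~3 sigma binomial at n=200

    def test_scenes_never_straddle_a_split(self):
        X, y, s = self._toy(n_scenes=11)
        table = lb.twofold_cv(X, y, s, model="max-margin", n_repeats=2, seed=4)
        # both images of a scene share every (repeat, fold) test assignment
        for rep in range(2):
            sub = table[table["repeat"] == rep]
            for scene in np.unique(s):
                idxs = np.flatnonzero(s == scene)
                assert len(sub[sub["image_index"].isin(idxs)]) == 2

    def test_logistic_with_pca_pipeline_runs(self):
        X, y, s = self._toy(n_scenes=30)
        X = np.hstack([X, X @ np.ones((3, 5))])  # redundant dims for PCA
        table = lb.twofold_cv(X, y, s, model="logistic", n_repeats=2, seed=5, pca_threshold=0.99)
        assert lb.cv_accuracy(table, y) > 0.9

    def test_unbalanced_labels_rejected(self):
        X, y, s = self._toy()
        with pytest.raises(ValueError):
            lb.twofold_cv(X, np.ones_like(y), s)
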