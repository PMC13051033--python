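"""The NumPy regression CNN: architecture, training, CV and Grad-CAM."""

import numpy as np
import pytest
from scipy import stats

from morphgaze import cnn

TINY = dict(input_size=(16, 16, 3), conv_filters=(4, 4, 8, 8, 8, 8), epochs=3, seed=0)


def _toy_data(rng, n=40, size=16):
    """Images whose mean brightness in the upper-left block encodes the label."""
    y = rng.uniform(-1, 1, n)
    imgs = np.full((n, size, size, 3), 128, np.uint8)
    for i in range(n):
        imgs[i, 2:8, 2:8] = np.clip(128 + 100 * y[i], 0, 255)
    return imgs, y.astype(np.float32)


class TestArchitecture:
    def test_parameter_count_is_config_function(self):
        a = cnn.build_scorer(cnn.CnnConfig(**TINY))
        b = cnn.build_scorer(cnn.CnnConfig(**{**TINY, "seed": 99}))
        assert a.n_parameters() == b.n_parameters()

    def test_forward_on_zeros_is_finite_scalar(self):
        m = cnn.build_scorer(cnn.CnnConfig(**TINY))
        out = m.forward(np.zeros((1, 3, 16, 16), np.float32))
        assert out.shape == (1,)
        assert np.isfinite(out[0])

    def test_spatial_size_halves_per_pool_stage(self):
        """Three pool stages (after convs 2, 4, 6) reduce each axis by 2^3."""
        m = cnn.build_scorer(cnn.CnnConfig(**{**TINY, "input_size": (32, 32, 3)}))
        x = np.zeros((1, 3, 32, 32), np.float32)
        for i, lay in enumerate(m.layers[:-1]):
            x = lay.forward(x, train=False)
        assert x.shape[2:] == (4, 4)  # 32 / 2^3
        # hand computation: dense input = 4*4*last_filters
        assert m.layers[-1].W.shape[0] == 4 * 4 * TINY["conv_filters"][-1]

    def test_incompatible_input_size_raises(self):
        with pytest.raises(ValueError, match="divisible|pooling"):
            cnn.CnnConfig(input_size=(20, 20, 3))

    def test_six_conv_layers_enforced(self):
        with pytest.raises(ValueError):
            cnn.CnnConfig(conv_filters=(8, 8, 8))


class TestTraining:
    def test_learns_brightness_signal(self, rng):
        imgs, y = _toy_data(rng, n=48)
        m = cnn.build_scorer(cnn.CnnConfig(**{**TINY, "epochs": 25}))
        cnn.train(m, imgs, y)
        r, _ = stats.pearsonr(cnn.predict(m, imgs), y)
        assert r > 0.95

    def test_shuffled_labels_do_not_generalize(self, rng):
        imgs, y = _toy_data(rng, n=48)
        y_shuf = rng.permutation(y)
        m = cnn.build_scorer(cnn.CnnConfig(**{**TINY, "epochs": 10}))
        cnn.train(m, imgs[:32], y_shuf[:32])
        pred = cnn.predict(m, imgs[32:])
        if np.std(pred) > 0:
            r, _ = stats.pearsonr(pred, y_shuf[32:])
            assert abs(r) < 0.6

    def test_same_seed_reproduces_history(self, rng):
        imgs, y = _toy_data(rng, n=20)
        hs = []
        for _ in range(2):
            m = cnn.build_scorer(cnn.CnnConfig(**TINY))
            cnn.train(m, imgs, y)
            hs.append(m.history)
        assert hs[0] == hs[1]

    def test_history_recorded_no_early_stop(self, rng):
        imgs, y = _toy_data(rng, n=20)
        m = cnn.build_scorer(cnn.CnnConfig(**{**TINY, "epochs": 7}))
        cnn.train(m, imgs, y)
        assert len(m.history) == 7

    def test_fine_tune_no_harm_and_provenance(self, rng):
        imgs, y = _toy_data(rng, n=32)
        base = cnn.build_scorer(cnn.CnnConfig(**{**TINY, "epochs": 10}))
        cnn.train(base, imgs, y)
        tuned = cnn.fine_tune(base, imgs, y, rater_group="male", epochs=5)
        assert tuned.provenance["role"] == "fine-tuned"
        assert tuned.provenance["rater_group"] == "male"
        # same data: loss does not regress beyond tolerance
        assert tuned.history[-1] <= base.history[-1] * 1.05 + 1e-4
        # base untouched
        assert base.provenance["role"] == "base"
        assert len(base.history) == 10

    def test_fine_tune_requires_trained_base(self):
        m = cnn.build_scorer(cnn.CnnConfig(**TINY))
        with pytest.raises(ValueError, match="trained"):
            cnn.fine_tune(m, np.zeros((4, 16, 16, 3), np.uint8), np.zeros(4))


class TestCrossValidation:
    def test_folds_disjoint_and_cover(self, rng):
        imgs, y = _toy_data(rng, n=23)
        rep = cnn.cross_validate(imgs, y, cnn.CnnConfig(**{**TINY, "epochs": 1}), k=5)
        all_idx = np.concatenate([np.array(f) for f in rep.folds])
        assert sorted(all_idx.tolist()) == list(range(23))
        assert len(rep.fold_r) == 5

    def test_noise_labels_near_zero_mean_r(self, rng):
        imgs, _ = _toy_data(rng, n=40)
        y = rng.normal(0, 1, 40)
        rep = cnn.cross_validate(imgs, y, cnn.CnnConfig(**{**TINY, "epochs": 3}), k=4)
        assert abs(rep.mean_r) < 0.5

    def test_reproducible_under_seed(self, rng):
        imgs, y = _toy_data(rng, n=20)
        cfg = cnn.CnnConfig(**{**TINY, "epochs": 1})
        r1 = cnn.cross_validate(imgs, y, cfg, k=4, seed=5)
        r2 = cnn.cross_validate(imgs, y, cfg, k=4, seed=5)
        assert r1.folds == r2.folds
        assert r1.fold_r == r2.fold_r


class TestGradCam:
    def test_zero_readout_gives_zero_map(self):
        m = cnn.build_scorer(cnn.CnnConfig(**TINY))
        m.layers[-1].W[:] = 0.0
        am = cnn.gradcam(m, np.full((16, 16, 3), 100, np.uint8))
        assert np.all(am.grid == 0)
        assert np.all(am.scale_0_255 == 0)

    def test_toy_network_closed_form(self):
        """A miniature with hand-set weights reproduces the hand-computed
        rectified weighted activation exactly (up to upsampling)."""
        cfg = cnn.CnnConfig(input_size=(8, 8, 1), conv_filters=(1, 1, 1, 1, 1, 2),
                            epochs=1, seed=0)
        m = cnn.build_scorer(cfg)
        # make every conv an identity pass-through and neutralize batch norm
        for lay in m.layers:
            if isinstance(lay, cnn._Conv):
                lay.W[:] = 0.0
                k = lay.k
                for co in range(lay.W.shape[0]):
                    w = lay.W[co].reshape(-1, k, k)
                    w[0, k // 2, k // 2] = 1.0
                lay.b[:] = 0.0
            elif isinstance(lay, cnn._BatchNorm):
                lay.run_mean[:] = 0.0
                lay.run_var[:] = 1.0 - lay.eps
        dense = m.layers[-1]
        dense.W[:] = 0.0
        dense.W[0, 0] = 2.0  # channel 0, top-left pooled cell

        img = np.zeros((8, 8, 1), np.uint8)
        img[0:2, 0:2] = 255
        am = cnn.gradcam(m, img)

        # hand computation.  Identity convs + pass-through batch norm turn the
        # cam layer (conv6 relu, after two pools) into 4x4-block maxima of
        # relu(x): a 2x2 grid with 0.5 in the top-left cell, both channels.
        act = np.array([[0.5, 0.0], [0.0, 0.0]])
        # gradient: dense weight 2 on pooled channel 0 routes to the argmax
        # cell; channel weights are spatial means of the gradient
        w0 = 2.0 / 4.0
        cam = np.maximum(w0 * act + 0.0 * act, 0)  # channel 1 weight is zero
        from skimage.transform import resize

        expected = resize(cam, (8, 8), order=1, mode="edge", anti_aliasing=False)
        assert np.allclose(am.grid, expected, atol=1e-6)

    def test_bias_shift_invariance(self, rng):
        imgs, y = _toy_data(rng, n=16)
        m = cnn.build_scorer(cnn.CnnConfig(**{**TINY, "epochs": 4}))
        cnn.train(m, imgs, y)
        a1 = cnn.gradcam(m, imgs[0]).grid
        m.layers[-1].b += 100.0
        a2 = cnn.gradcam(m, imgs[0]).grid
        assert np.allclose(a1, a2)

    def test_maps_nonnegative(self, rng):
        imgs, y = _toy_data(rng, n=16)
        m = cnn.build_scorer(cnn.CnnConfig(**{**TINY, "epochs": 2}))
        cnn.train(m, imgs, y)
        for i in range(3):
            assert (cnn.gradcam(m, imgs[i]).grid >= 0).all()


class TestAttentionSignificance:
    def test_all_zero_maps_empty_mask(self):
        maps = [np.zeros((8, 8)) for _ in range(5)]
        assert not cnn.attention_significance(maps).any()

    def test_planted_block_recovered(self, rng):
        maps = []
        for _ in range(12):
            g = rng.normal(0, 1.0, (16, 16))
            g[4:8, 4:8] += 5.0
            maps.append(g)
        mask = cnn.attention_significance(maps, q=0.05)
        planted = np.zeros((16, 16), bool)
        planted[4:8, 4:8] = True
        jac = (mask & planted).sum() / max((mask | planted).sum(), 1)
        assert jac > 0.5

    def test_bh_mask_monotone_in_q(self, rng):
        maps = [rng.normal(0.2, 1.0, (10, 10)) for _ in range(8)]
        m1 = cnn.attention_significance(maps, q=0.01)
        m5 = cnn.attention_significance(maps, q=0.05)
        assert not (m1 & ~m5).any()
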