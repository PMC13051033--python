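"""The synthetic world: template, population, rendering, ratings, gaze."""

import numpy as np
import pytest

from morphgaze import synth as sy
from morphgaze import shape_core as sc


class TestTemplate:
    def test_counts_and_bounds(self, template):
        assert template.points_main.shape == (52, 2)
        assert template.points_semi.shape == (87, 2)
        for pts in (template.points_main, template.points_semi):
            assert pts.min() >= 0 and pts.max() <= 1

    def test_bilateral_symmetry_permutation(self, template):
        mirrored = template.points_main.copy()
        mirrored[:, 0] = 1.0 - mirrored[:, 0]
        assert np.abs(mirrored[template.mirror_permutation] - template.points_main).max() < 1e-12

    def test_deterministic(self):
        a = sy.make_template()
        b = sy.make_template()
        assert np.array_equal(a.points_main, b.points_main)
        assert np.array_equal(a.points_semi, b.points_semi)

    def test_no_duplicate_control_points(self, template):
        pts = np.vstack([template.points_main, template.points_semi])
        d2 = ((pts[:, None] - pts[None]) ** 2).sum(-1)
        iu = np.triu_indices(len(pts), 1)
        assert d2[iu].min() > 1e-8


class TestPopulation:
    def test_same_seed_identical(self):
        cfg = sy.SyntheticWorldConfig(n_faces=8, seed=5)
        a = sy.sample_population(cfg)
        b = sy.sample_population(cfg)
        assert np.array_equal(a[1], b[1])
        for ca, cb in zip(a[0], b[0]):
            assert np.array_equal(ca.points_main, cb.points_main)

    def test_pure_shape_beta_orthogonal_to_similarity(self, template):
        beta = sy.default_beta(template)
        q = sy.similarity_basis(template.points_main)
        assert np.abs(q @ beta.ravel()).max() < 1e-12

    def test_truth_ledger_supports_every_estimator(self):
        """Closure: the ledger carries enough latents to predict what each
        pipeline estimator should return."""
        cfg = sy.SyntheticWorldConfig(n_faces=12, seed=1)
        _, scores, truth = sy.sample_population(cfg)
        for key in ("beta_true", "scores", "noise_sd", "score_sd",
                    "planned_variance_explained_pct"):
            assert key in truth
        design = sy.make_design(
            sy.SyntheticWorldConfig(seed=1, n_participants_male=2,
                                    n_participants_female=2, n_trials_per_participant=12)
        )
        _, rt = sy.simulate_ratings(design, cfg)
        for key in ("slope_morph", "image_sex_effect", "participant_intercepts",
                    "stimulus_intercepts", "residual_sd"):
            assert key in rt


class TestRender:
    def test_identical_landmarks_pixel_identical(self, template):
        a = sy.render_face(template.configuration(), 96, template)
        b = sy.render_face(template.configuration(), 96, template)
        assert np.array_equal(a.pixels, b.pixels)

    def test_eyebrow_morph_moves_rendered_eyebrow(self, template):
        """Raising the eyebrows by a known pixel displacement moves the dark
        eyebrow pixels' centroid by that amount (within a pixel)."""
        size = 128
        base = sy.render_face(template.configuration(), size, template)
        beta = sy.default_beta(template, pure_shape=False)
        shift_units = 3.0 * 0.7 * 0.012  # 3 SD * score sd * magnitude, upward
        cfg = template.configuration()
        cfg.points_main = cfg.points_main + 3.0 * 0.7 * beta
        morphed = sy.render_face(cfg, size, template)

        def brow_centroid_y(img):
            dark = img.pixels[:, :, 0] <= sy.FEATURE_SHADE["eyebrow"] + 5
            rows = np.where(dark.any(axis=1))[0]
            upper = dark[: rows.min() + 12]  # isolate the brow band
            ys = np.nonzero(upper)[0]
            return ys.mean()

        dy = brow_centroid_y(morphed) - brow_centroid_y(base)
        assert dy == pytest.approx(-shift_units * size, abs=1.0)

    def test_locality_of_differences(self, template):
        """An eyebrow-only displacement changes pixels only near the eyebrows."""
        size = 128
        base = sy.render_face(template.configuration(), size, template)
        beta = sy.default_beta(template, pure_shape=False)
        cfg = template.configuration()
        cfg.points_main = cfg.points_main + 2.0 * beta
        morphed = sy.render_face(cfg, size, template)
        diff = (base.pixels != morphed.pixels).any(axis=-1)
        idx = np.concatenate([template.groups["eyebrow_left"], template.groups["eyebrow_right"]])
        ys = template.points_main[idx, 1] * size
        band = np.zeros(size, bool)
        lo = int(ys.min() - 0.05 * size)
        hi = int(ys.max() + 0.05 * size)
        band[max(lo, 0) : hi + 1] = True
        assert diff[~band].sum() == 0

    def test_out_of_canvas_raises(self, template):
        cfg = template.configuration()
        cfg.points_main = cfg.points_main + 0.9
        with pytest.raises(ValueError, match="canvas"):
            sy.render_face(cfg, 64, template)


class TestRatings:
    def test_deterministic_when_noiseless(self):
        cfg = sy.SyntheticWorldConfig(
            seed=2, residual_sd=0.0, participant_intercept_sd=0.0, stimulus_intercept_sd=0.0,
            n_participants_male=2, n_participants_female=2, n_trials_per_participant=15,
        )
        design = sy.make_design(cfg)
        rated, _ = sy.simulate_ratings(design, cfg)
        expected = np.clip(
            np.rint(
                cfg.rating_grand_mean
                + cfg.slope_morph * rated.level_sd
                + cfg.image_sex_effect * rated.image_sex.map({"male": -0.5, "female": 0.5})
            ),
            1, 7,
        )
        assert (rated.rating == expected).all()

    def test_extreme_slope_clips_to_scale(self):
        cfg = sy.SyntheticWorldConfig(
            seed=3, slope_morph=5.0, n_participants_male=2, n_participants_female=2,
            n_trials_per_participant=15,
        )
        rated, _ = sy.simulate_ratings(sy.make_design(cfg), cfg)
        assert rated.rating.min() >= 1 and rated.rating.max() <= 7
        assert (rated.rating == 1).any() and (rated.rating == 7).any()


class TestGaze:
    def test_pure_function_of_seed(self, template):
        cfg = sy.SyntheticWorldConfig(seed=4)
        centers = {k: v.mean(axis=0) * 128 for k, v in sy.template_aoi_points(template).items()}
        a, ta = sy.simulate_gaze(cfg, centers, (128, 128), np.random.default_rng(9))
        b, tb = sy.simulate_gaze(cfg, centers, (128, 128), np.random.default_rng(9))
        assert a.equals(b)
        assert ta["n_fixations"] == tb["n_fixations"]

    def test_stream_covers_viewing_window(self, template):
        cfg = sy.SyntheticWorldConfig(seed=5)
        centers = {k: v.mean(axis=0) * 128 for k, v in sy.template_aoi_points(template).items()}
        df, _ = sy.simulate_gaze(cfg, centers, (128, 128), np.random.default_rng(1))
        assert df.t_ms.iloc[0] == 0.0
        assert df.t_ms.iloc[-1] <= cfg.viewing_ms
        assert len(df) == pytest.approx(cfg.viewing_ms / 1000 * cfg.sampling_rate, abs=2)
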