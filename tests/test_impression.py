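"""Shape-on-score regression, permutation significance and morph targets."""

import numpy as np
import pytest

from morphgaze import impression as imp
from morphgaze import shape_core as sc
from morphgaze import synth as sy


def _labels(configs, scores, trait="dominance"):
    return [
        imp.ImpressionLabel(image_id=c.image_id, trait=trait, score=float(s))
        for c, s in zip(configs, scores)
    ]


@pytest.fixture(scope="module")
def fitted(aligned_small_mod, pop_mod):
    configs, scores, _ = pop_mod
    return imp.fit_shape_regression(aligned_small_mod, _labels(configs, scores))


@pytest.fixture(scope="module")
def pop_mod():
    cfg = sy.SyntheticWorldConfig(n_faces=40, seed=21)
    return sy.sample_population(cfg)


@pytest.fixture(scope="module")
def aligned_small_mod(pop_mod):
    return sc.gpa_align(pop_mod[0])


class TestFit:
    def test_zero_score_variance_raises(self, aligned_small_mod, pop_mod):
        configs, scores, _ = pop_mod
        labels = _labels(configs, np.full_like(scores, 4.0))
        with pytest.raises(ValueError, match="variance"):
            imp.fit_shape_regression(aligned_small_mod, labels)

    def test_missing_labels_listed(self, aligned_small_mod, pop_mod):
        configs, scores, _ = pop_mod
        labels = _labels(configs, scores)[:-2]
        with pytest.raises(ValueError, match=configs[-1].image_id):
            imp.fit_shape_regression(aligned_small_mod, labels)

    def test_parameter_recovery_n300(self):
        """With 300 faces and 10% noise the slope field matches the generator's
        displacement field at r >= 0.95."""
        cfg = sy.SyntheticWorldConfig(n_faces=300, seed=2)
        configs, scores, truth = sy.sample_population(cfg)
        al = sc.gpa_align(configs)
        model = imp.fit_shape_regression(al, _labels(configs, scores))
        r = np.corrcoef(model.slopes.ravel(), truth["beta_true"].ravel())[0, 1]
        assert r >= 0.95

    def test_noiseless_recovery_in_linear_regime(self):
        """Without landmark noise and with a small displacement the slope field
        is essentially exact (the superimposition is locally linear)."""
        cfg = sy.SyntheticWorldConfig(
            n_faces=100, seed=5, landmark_noise_sd=0.0, beta_magnitude=0.004
        )
        configs, scores, truth = sy.sample_population(cfg)
        al = sc.gpa_align(configs)
        model = imp.fit_shape_regression(al, _labels(configs, scores))
        r = np.corrcoef(model.slopes.ravel(), truth["beta_true"].ravel())[0, 1]
        assert r >= 0.999

    def test_variance_explained_invariant_to_score_rescaling(self, aligned_small_mod, pop_mod):
        configs, scores, _ = pop_mod
        m1 = imp.fit_shape_regression(aligned_small_mod, _labels(configs, scores))
        rescaled = 1.0 + (scores - 1.0) * 0.5  # affine map into the scale
        m2 = imp.fit_shape_regression(aligned_small_mod, _labels(configs, rescaled))
        assert m1.variance_explained_pct == pytest.approx(m2.variance_explained_pct, rel=1e-10)
        # slopes and score SD rescale inversely
        assert np.allclose(m1.slopes * m1.score_sd, m2.slopes * m2.score_sd)

    def test_estimated_variance_tracks_planned_value(self):
        """|estimated - planned| variance explained shrinks as n grows."""
        bias = []
        for n in (50, 150, 500):
            errs = []
            for rep in range(8):
                cfg = sy.SyntheticWorldConfig(n_faces=n, seed=1000 + 17 * rep + n)
                configs, scores, truth = sy.sample_population(cfg)
                al = sc.gpa_align(configs)
                m = imp.fit_shape_regression(al, _labels(configs, scores))
                errs.append(abs(m.variance_explained_pct - truth["planned_variance_explained_pct"]))
            bias.append(np.mean(errs))
        assert bias[2] < bias[0]

    def test_json_round_trip(self, fitted, tmp_path):
        fitted.to_json(tmp_path / "m.json")
        back = imp.ShapeRegressionModel.from_json(tmp_path / "m.json")
        assert np.allclose(back.slopes, fitted.slopes)
        assert back.variance_explained_pct == pytest.approx(fitted.variance_explained_pct)


class TestPermutation:
    def test_extreme_case_minimum_p(self, aligned_small_mod, pop_mod):
        """A strong true effect beats every permutation: p = 1/(n_perm+1)."""
        configs, scores, _ = pop_mod
        p = imp.permutation_test(aligned_small_mod, _labels(configs, scores), n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_determinism_under_seed(self, aligned_small_mod, pop_mod):
        configs, scores, _ = pop_mod
        labels = _labels(configs, scores)
        p1 = imp.permutation_test(aligned_small_mod, labels, n_perm=199, seed=42)
        p2 = imp.permutation_test(aligned_small_mod, labels, n_perm=199, seed=42)
        assert p1 == p2

    def test_invalid_n_perm(self, aligned_small_mod, pop_mod):
        configs, scores, _ = pop_mod
        with pytest.raises(ValueError):
            imp.permutation_test(aligned_small_mod, _labels(configs, scores), n_perm=0)

    def test_null_p_values_roughly_uniform(self):
        """Scores independent of shape give a null p distribution that is not
        concentrated (coarse check; the full calibration lives in acceptance)."""
        rng = np.random.default_rng(7)
        cfg = sy.SyntheticWorldConfig(n_faces=25, seed=3, beta_magnitude=0.0)
        configs, scores, _ = sy.sample_population(cfg)
        al = sc.gpa_align(configs)
        ps = []
        for rep in range(40):
            perm_scores = rng.permutation(scores) + rng.normal(0, 1e-6, len(scores))
            perm_scores = np.clip(perm_scores, 1, 7)
            ps.append(
                imp.permutation_test(al, _labels(configs, perm_scores), n_perm=99, seed=rep)
            )
        assert 0.2 < np.mean(ps) < 0.8


class TestMorph:
    def test_level_zero_is_mean_shape(self, fitted):
        out = imp.predict_mean_morph(fitted, 0.0)
        assert np.array_equal(out.points_main, fitted.mean_shape)

    def test_antisymmetry_and_linearity(self, fitted):
        for k in (1.5, 3.0):
            up = imp.predict_mean_morph(fitted, k).points_main - fitted.mean_shape
            dn = imp.predict_mean_morph(fitted, -k).points_main - fitted.mean_shape
            assert np.allclose(up, -dn)
        d3 = imp.predict_mean_morph(fitted, 3.0).points_main - fitted.mean_shape
        d15 = imp.predict_mean_morph(fitted, 1.5).points_main - fitted.mean_shape
        assert np.allclose(d3, 2 * d15)

    def test_face_target_level_zero_recovers_own_landmarks(
        self, fitted, aligned_small_mod, pop_mod
    ):
        configs, _, _ = pop_mod
        i = 4
        out = imp.morph_target_for_face(
            fitted,
            aligned_small_mod.aligned[i],
            aligned_small_mod.transforms[i],
            0.0,
            semi_image_space=configs[i].points_semi,
        )
        assert np.abs(out.points_main - configs[i].points_main).max() < 1e-6
        assert np.abs(out.points_semi - configs[i].points_semi).max() < 1e-6

    def test_targets_differ_between_faces(self, fitted, aligned_small_mod):
        a = imp.morph_target_for_face(
            fitted, aligned_small_mod.aligned[0], aligned_small_mod.transforms[0], 3.0
        )
        b = imp.morph_target_for_face(
            fitted, aligned_small_mod.aligned[1], aligned_small_mod.transforms[1], 3.0
        )
        assert not np.allclose(a.points_main, b.points_main)

    def test_pixel_displacement_scales_with_procrustes_scale(self, fitted):
        """Hand-composed transform oracle: doubling a face's Procrustes scale
        doubles the pixel-space morph displacement."""
        tr1 = sc.SimilarityTransform(
            translation=np.array([10.0, 20.0]), scale=100.0, rotation=np.eye(2)
        )
        tr2 = sc.SimilarityTransform(
            translation=np.array([10.0, 20.0]), scale=200.0, rotation=np.eye(2)
        )
        face = fitted.mean_shape
        d1 = imp.morph_target_for_face(fitted, face, tr1, 3.0).points_main - tr1.to_image(face)
        d2 = imp.morph_target_for_face(fitted, face, tr2, 3.0).points_main - tr2.to_image(face)
        assert np.allclose(d2, 2 * d1)
        # oracle: displacement = slopes * 3 * sd, pushed through the transform's scale
        expected = fitted.slopes * 3.0 * fitted.score_sd * 100.0
        assert np.allclose(d1, expected)

    def test_missing_transform_raises(self, fitted):
        with pytest.raises(ValueError, match="transform"):
            imp.morph_target_for_face(fitted, fitted.mean_shape, None, 1.0)
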