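"""Heatmap normalization, KLD, AOIs and difference maps."""

import numpy as np
import pytest

from morphgaze import compare as cp
from morphgaze import synth as sy


class TestNormalize:
    def test_uniform_map(self):
        d = cp.normalize_distribution(np.ones((8, 10)))
        assert np.allclose(d.probs, 1.0 / 80)

    def test_sums_to_one_any_input(self, rng):
        for _ in range(10):
            g = rng.gamma(1.0, 1.0, (12, 9))
            d = cp.normalize_distribution(g)
            assert d.probs.sum() == pytest.approx(1.0, abs=1e-9)
            assert (d.probs > 0).all()

    def test_scale_invariance(self, rng):
        g = rng.gamma(1.0, 1.0, (6, 6)) + 0.5
        d1 = cp.normalize_distribution(g)
        d2 = cp.normalize_distribution(2 * g)
        assert np.abs(d1.probs - d2.probs).max() < 1e-6

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            cp.normalize_distribution(np.zeros((4, 4)))


class TestKld:
    def test_identical_distributions_zero(self, rng):
        d = cp.normalize_distribution(rng.random((5, 5)) + 0.1)
        assert cp.kld(d, d) == 0.0

    def test_two_cell_closed_form(self):
        P = cp.HeatmapDistribution(np.array([[0.9, 0.1]]), 0.0, "fixation")
        Q = cp.HeatmapDistribution(np.array([[0.5, 0.5]]), 0.0, "gradcam")
        expected = 0.9 * np.log(1.8) + 0.1 * np.log(0.2)
        assert cp.kld(P, Q) == pytest.approx(expected, abs=1e-12)
        assert cp.kld(P, Q) == pytest.approx(0.368, abs=5e-4)

    def test_nonnegative_and_asymmetric(self, rng):
        """Gibbs' inequality over many random pairs; asymmetry in general."""
        for _ in range(300):
            p = cp.normalize_distribution(rng.random((4, 6)) + 1e-3)
            q = cp.normalize_distribution(rng.random((4, 6)) + 1e-3)
            assert cp.kld(p, q) >= 0
        assert cp.kld(p, q) != pytest.approx(cp.kld(q, p), rel=1e-3)

    def test_geometry_mismatch_raises(self, rng):
        p = cp.normalize_distribution(rng.random((4, 4)) + 0.1)
        q = cp.normalize_distribution(rng.random((5, 5)) + 0.1)
        with pytest.raises(ValueError, match="geometry"):
            cp.kld(p, q)


class TestAoi:
    def test_template_aois_nonempty_and_within_raster(self, template):
        pts = {k: v * 128 for k, v in sy.template_aoi_points(template).items()}
        aois = cp.aois_from_points(pts, (128, 128), dilate_radius=3)
        assert set(aois.names) == set(cp.AOI_NAMES)
        for mask in aois.masks.values():
            assert mask.any()
            assert mask.shape == (128, 128)

    def test_masses_sum_to_total_on_partition(self, rng):
        grid = rng.random((32, 32))
        masks = {
            "left": np.zeros((32, 32), bool),
            "right": np.zeros((32, 32), bool),
        }
        masks["left"][:, :16] = True
        masks["right"][:, 16:] = True
        aois = cp.AoiSet(masks=masks)
        m = cp.aoi_mass(grid, aois)
        assert sum(m.values()) == pytest.approx(grid.sum())

    def test_proportional_masses_give_r_one(self, template, rng):
        pts = {k: v * 64 for k, v in sy.template_aoi_points(template).items()}
        aois = cp.aois_from_points(pts, (64, 64), dilate_radius=2)
        fix = rng.random((64, 64))
        att = 3.0 * fix  # proportional mass in every AOI
        r, p, n = cp.aoi_correlation(fix, att, aois)
        assert r == pytest.approx(1.0)
        assert n == len(cp.AOI_NAMES)

    def test_anti_ordered_masses_negative_r(self):
        masks = {f"m{i}": np.zeros((10, 10), bool) for i in range(4)}
        for i in range(4):
            masks[f"m{i}"][i, :] = True
        aois = cp.AoiSet(masks=masks)
        fix = np.zeros((10, 10))
        att = np.zeros((10, 10))
        for i in range(4):
            fix[i, :] = i + 1
            att[i, :] = 4 - i
        r, _, _ = cp.aoi_correlation(fix, att, aois)
        assert r < 0

    def test_zero_variance_flagged(self):
        masks = {f"m{i}": np.zeros((6, 6), bool) for i in range(3)}
        for i in range(3):
            masks[f"m{i}"][i, i] = True
        aois = cp.AoiSet(masks=masks)
        r, p, n = cp.aoi_correlation(np.ones((6, 6)), np.ones((6, 6)), aois)
        assert r is None and p is None

    def test_independent_weights_give_small_mean_abs_r(self, template, rng):
        """Gaze and attention with independent AOI weight draws show no
        systematic correlation (pooled over conditions within each set)."""
        pts = {k: v * 128 for k, v in sy.template_aoi_points(template).items()}
        aois = cp.aois_from_points(pts, (128, 128), dilate_radius=5, exclusive=True)
        rs = []
        for _ in range(40):
            fix = [_aoi_mixture_grid(rng, aois, rng.dirichlet(np.ones(8))) for _ in range(4)]
            att = [_aoi_mixture_grid(rng, aois, rng.dirichlet(np.ones(8))) for _ in range(4)]
            r, _, n = cp.aoi_correlation(fix, att, aois)
            rs.append(r)
        assert n == 32
        assert np.mean(np.abs(rs)) < 0.25
        assert abs(np.mean(rs)) < 0.15


class TestDifferenceMap:
    def test_identical_sets_zero(self, rng):
        maps = [rng.random((6, 6)) for _ in range(4)]
        assert np.allclose(cp.difference_map(maps, maps), 0)

    def test_antisymmetry(self, rng):
        a = [rng.random((6, 6)) for _ in range(3)]
        b = [rng.random((6, 6)) for _ in range(3)]
        assert np.allclose(cp.difference_map(a, b), -cp.difference_map(b, a))

    def test_geometry_mismatch(self, rng):
        with pytest.raises(ValueError):
            cp.difference_map([rng.random((4, 4))], [rng.random((5, 5))])


def _aoi_mixture_grid(rng, aois, weights, n_samples=80, sigma=1.5):
    """Duration-style map: samples land uniformly inside AOIs drawn by weight."""
    from scipy.ndimage import gaussian_filter

    names = aois.names
    shape = aois.masks[names[0]].shape
    coords = {n: np.argwhere(aois.masks[n]) for n in names}
    g = np.zeros(shape)
    for k in rng.choice(len(names), size=n_samples, p=weights):
        cs = coords[names[k]]
        r, c = cs[rng.integers(len(cs))]
        g[r, c] += 1.0
    return gaussian_filter(g, sigma)


def test_shared_generator_kld_smaller_than_independent(template, rng):
    """Maps built from one AOI weight vector are closer (in KLD) than maps from
    independent weight vectors; coarse check of the ordering."""
    pts = {k: v * 128 for k, v in sy.template_aoi_points(template).items()}
    aois = cp.aois_from_points(pts, (128, 128), dilate_radius=5, exclusive=True)

    wins = 0
    within, between = [], []
    n = 30
    for _ in range(n):
        w_shared = rng.dirichlet(np.ones(8))
        w_other = rng.dirichlet(np.ones(8))
        a = cp.normalize_distribution(_aoi_mixture_grid(rng, aois, w_shared, 500, 3.0))
        b = cp.normalize_distribution(_aoi_mixture_grid(rng, aois, w_shared, 500, 3.0))
        c = cp.normalize_distribution(_aoi_mixture_grid(rng, aois, w_other, 500, 3.0))
        within.append(cp.kld(a, b))
        between.append(cp.kld(a, c))
        wins += within[-1] < between[-1]
    assert wins >= round(0.9 * n)
    assert np.mean(within) < 1.0  # shared-generator maps are close in KLD terms
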