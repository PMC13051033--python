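"""Comparing human fixation maps with model attention maps.

Both kinds of map are non-negative pixel grids over the same raster; to compare
them they are epsilon-smoothed and normalized into probability distributions
(sum 1), after which Kullback-Leibler divergence quantifies their discrepancy.
KLD is asymmetric, so every report labels its direction; the default direction
is D(fixation || attention) and both directions plus the symmetrized mean are
emitted.  A coarser comparison aggregates each map's mass over named facial
areas of interest (AOIs) and correlates the two mass vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as draw_polygon
from skimage.morphology import dilation, disk

__all__ = [
    "HeatmapDistribution",
    "AoiSet",
    "ComparisonResult",
    "normalize_distribution",
    "kld",
    "aoi_mass",
    "aoi_correlation",
    "difference_map",
    "aois_from_points",
]

AOI_NAMES = ("eyes", "eyebrows", "glabella", "nose", "mouth", "cheeks", "chin", "forehead")


@dataclass
class HeatmapDistribution:
    probs: np.ndarray  # (H, W), strictly positive, sums to 1
    epsilon: float
    source_kind: str  # "fixation" | "gradcam"
    condition: dict = field(default_factory=dict)


@dataclass
class AoiSet:
    """Named boolean masks over the stimulus raster; overlaps allowed but reported."""

    masks: dict  # name -> (H, W) bool

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("AOI masks must share one raster geometry")
        for name, m in self.masks.items():
            if not m.any():
                raise ValueError(f"AOI {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.masks)

    def overlap_report(self) -> dict:
        names = self.names
        out = {}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                n = int((self.masks[a] & self.masks[b]).sum())
                if n:
                    out[(a, b)] = n
        return out


@dataclass
class ComparisonResult:
    kld_fix_vs_att: float  # D(fixation || attention)
    kld_att_vs_fix: float
    kld_symmetric: float
    aoi_r: float | None = None
    aoi_p: float | None = None
    n_aoi: int = 0
    condition: dict = field(default_factory=dict)


def normalize_distribution(
    grid: np.ndarray,
    epsilon: float = 1e-8,
    source_kind: str = "fixation",
    condition: dict | None = None,
) -> HeatmapDistribution:
    """Turn a non-negative map into a strictly positive probability grid.

    ``epsilon`` is added to every cell before dividing by the total, so empty
    cells never produce infinite divergences; the value used is recorded.
    """
    g = np.asarray(grid, dtype=float)
    if np.any(g < 0) or not np.all(np.isfinite(g)):
        raise ValueError("map must be non-negative and finite")
    if g.sum() == 0:
        raise ValueError("cannot normalize an all-zero map")
    p = g + epsilon
    p = p / p.sum()
    return HeatmapDistribution(
        probs=p, epsilon=epsilon, source_kind=source_kind, condition=condition or {}
    )


def kld(P: HeatmapDistribution, Q: HeatmapDistribution) -> float:
    """Kullback-Leibler divergence D(P || Q) in nats (natural log)."""
    if P.probs.shape != Q.probs.shape:
        raise ValueError(f"geometry mismatch: {P.probs.shape} vs {Q.probs.shape}")
    return float(np.sum(P.probs * np.log(P.probs / Q.probs)))


def compare_maps(
    fixation_grid: np.ndarray,
    attention_grid: np.ndarray,
    aois: AoiSet | None = None,
    epsilon: float = 1e-8,
    condition: dict | None = None,
) -> ComparisonResult:
    """Full comparison of one fixation map against one attention map."""
    P = normalize_distribution(fixation_grid, epsilon, "fixation", condition)
    Q = normalize_distribution(attention_grid, epsilon, "gradcam", condition)
    fw = kld(P, Q)
    bw = kld(Q, P)
    res = ComparisonResult(
        kld_fix_vs_att=fw,
        kld_att_vs_fix=bw,
        kld_symmetric=0.5 * (fw + bw),
        condition=condition or {},
    )
    if aois is not None:
        r, p, n = aoi_correlation(fixation_grid, attention_grid, aois)
        res.aoi_r, res.aoi_p, res.n_aoi = r, p, n
    return res


def aoi_mass(grid: np.ndarray, aois: AoiSet) -> dict:
    """Total map mass inside each AOI."""
    return {name: float(grid[mask].sum()) for name, mask in aois.masks.items()}


def aoi_correlation(fix_grids, att_grids, aois: AoiSet):
    """Pearson correlation of per-AOI fixation mass against attention mass.

    Accepts a single map pair or matched lists of condition maps; with lists
    the (AOI x condition) mass pairs are pooled into one correlation.  Each
    map's masses are normalized to its own total mass first, so conditions with
    more gaze do not dominate.  Returns (r, two-tailed p, n_pairs); r is None
    (flagged) if either mass vector has zero variance.
    """
    if len(aois.masks) < 3:
        raise ValueError("need >= 3 AOIs for a correlation")
    if isinstance(fix_grids, np.ndarray) and fix_grids.ndim == 2:
        fix_grids = [fix_grids]
        att_grids = [att_grids]
    if len(fix_grids) != len(att_grids):
        raise ValueError("condition lists must be matched")
    f, a = [], []
    for fg, ag in zip(fix_grids, att_grids):
        fm = np.array(list(aoi_mass(np.asarray(fg), aois).values()))
        am = np.array(list(aoi_mass(np.asarray(ag), aois).values()))
        f.append(fm / fm.sum() if fm.sum() else fm)
        a.append(am / am.sum() if am.sum() else am)
    f = np.concatenate(f)
    a = np.concatenate(a)
    if np.std(f) == 0 or np.std(a) == 0:
        return None, None, len(f)
    r, p = stats.pearsonr(f, a)
    return float(r), float(p), len(f)


def difference_map(maps_a, maps_b) -> np.ndarray:
    """mean(maps_a) - mean(maps_b), a signed per-pixel contrast grid."""
    A = np.stack([np.asarray(getattr(m, "grid", m), dtype=float) for m in maps_a])
    B = np.stack([np.asarray(getattr(m, "grid", m), dtype=float) for m in maps_b])
    if A.shape[1:] != B.shape[1:]:
        raise ValueError(f"geometry mismatch: {A.shape[1:]} vs {B.shape[1:]}")
    return A.mean(axis=0) - B.mean(axis=0)


def _points_mask(points: np.ndarray, shape: tuple[int, int], dilate_radius: int) -> np.ndarray:
    """Dilated convex-hull mask of a point set (falls back to dilated points)."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(points, dtype=float)
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            rr, cc = draw_polygon(pts[hull.vertices, 1], pts[hull.vertices, 0], shape)
            mask[rr, cc] = True
        except QhullError:
            pass
    if not mask.any():
        rr = np.clip(np.rint(pts[:, 1]).astype(int), 0, h - 1)
        cc = np.clip(np.rint(pts[:, 0]).astype(int), 0, w - 1)
        mask[rr, cc] = True
    if dilate_radius > 0:
        mask = dilation(mask, disk(dilate_radius))
    return mask


def aois_from_points(
    points_by_name: dict,
    shape: tuple[int, int],
    dilate_radius: int = 3,
    exclusive: bool = False,
) -> AoiSet:
    """Build an AOI set from named landmark point groups.

    Each AOI is the convex hull of its points, rasterized and dilated by
    ``dilate_radius`` pixels (the hull of facial landmarks is tight around the
    feature; dilation restores a margin of surrounding skin).  With
    ``exclusive=True`` pixels claimed by several AOIs are assigned to the
    nearest feature only, yielding disjoint masks whose masses partition the
    covered map mass — the right footing for correlating mass vectors.
    """
    masks = {
        name: _points_mask(np.asarray(pts), shape, dilate_radius)
        for name, pts in points_by_name.items()
    }
    if exclusive:
        names = list(masks)
        dist = np.stack(
            [ndi_distance(masks[n], points_by_name[n], shape) for n in names]
        )
        claimed = np.stack([masks[n] for n in names])
        n_claims = claimed.sum(axis=0)
        overlap = n_claims > 1
        if overlap.any():
            winner = np.argmin(np.where(claimed, dist, np.inf), axis=0)
            for i, n in enumerate(names):
                masks[n] = masks[n] & (~overlap | (winner == i))
    return AoiSet(masks=masks)


def ndi_distance(mask: np.ndarray, points, shape) -> np.ndarray:
    """Pixel distance to the nearest of the AOI's defining points."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.asarray(points, dtype=float)
    d2 = np.min(
        (xs[None] - pts[:, 0, None, None]) ** 2 + (ys[None] - pts[:, 1, None, None]) ** 2,
        axis=0,
    )
    return np.sqrt(d2)
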