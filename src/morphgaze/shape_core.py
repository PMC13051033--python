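"""Landmark geometry: Procrustes superimposition and thin-plate splines.

Coordinates are 2-D image pixels, origin at the top-left corner, y increasing
downward, 0-based.  A face is digitized as an ordered set of *main* landmarks
(anatomically homologous points entering all shape statistics) plus an ordered
set of *semi-landmarks* (contour points carried along only for smooth imaging;
they take no part in superimposition or regression).

Generalized Procrustes analysis (GPA) removes translation, scale and rotation
from a sample of landmark configurations so that the residual variation is
shape.  The thin-plate spline (TPS) is the minimum-bending-energy interpolant
between two landmark sets; it is used both to transport semi-landmarks when a
shape is deformed and to warp dense pixel grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandmarkConfiguration",
    "SimilarityTransform",
    "AlignedShapeSet",
    "TpsWarp",
    "centroid_size",
    "gpa_align",
    "tps_fit",
    "tps_apply",
]


def _as_points(a, name: str = "points") -> np.ndarray:
    pts = np.asarray(a, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"{name} must be a k x 2 array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return pts


@dataclass
class LandmarkConfiguration:
    """One face's 2-D landmark coordinates (main + semi) in image pixels."""

    points_main: np.ndarray
    points_semi: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    image_id: str = ""
    scale_px_per_unit: float | None = None

    def __post_init__(self) -> None:
        self.points_main = _as_points(self.points_main, "points_main")
        self.points_semi = _as_points(self.points_semi, "points_semi")
        if self.scale_px_per_unit is not None and self.scale_px_per_unit <= 0:
            raise ValueError("scale_px_per_unit must be positive")

    @property
    def n_main(self) -> int:
        return len(self.points_main)

    @property
    def n_semi(self) -> int:
        return len(self.points_semi)

    @property
    def all_points(self) -> np.ndarray:
        return np.vstack([self.points_main, self.points_semi])


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks from their centroid."""
    pts = _as_points(points)
    centered = pts - pts.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


@dataclass
class SimilarityTransform:
    """Maps an aligned (unit-size, centered, rotated) shape back to image space.

    raw = aligned @ rotation.T * scale + translation
    """

    translation: np.ndarray  # (2,) centroid of the raw shape
    scale: float  # centroid size of the raw shape
    rotation: np.ndarray  # (2, 2) applied during alignment

    def to_aligned(self, raw: np.ndarray) -> np.ndarray:
        return ((raw - self.translation) / self.scale) @ self.rotation

    def to_image(self, aligned: np.ndarray) -> np.ndarray:
        return aligned @ self.rotation.T * self.scale + self.translation


@dataclass
class AlignedShapeSet:
    """Result of generalized Procrustes superimposition."""

    aligned: np.ndarray  # (n, k, 2)
    mean_shape: np.ndarray  # (k, 2), coordinate-wise mean of `aligned`
    centroid_sizes: np.ndarray  # (n,)
    transforms: list[SimilarityTransform]
    image_ids: list[str]
    n_iterations: int = 0

    @property
    def n_shapes(self) -> int:
        return self.aligned.shape[0]

    @property
    def residuals(self) -> np.ndarray:
        """Procrustes residuals (aligned minus mean), the 'warp' variables."""
        return self.aligned - self.mean_shape[None]

    def tangent_projected(self) -> np.ndarray:
        """Orthogonal projection of aligned shapes onto the tangent space at the mean.

        Off by default throughout the pipeline (shape variation in face samples
        is small); exposed for sensitivity checks.
        """
        mu = self.mean_shape.ravel()
        mu = mu / np.linalg.norm(mu)
        flat = self.aligned.reshape(self.n_shapes, -1)
        proj = flat - np.outer(flat @ mu, mu) + mu
        return proj.reshape(self.aligned.shape)


def _optimal_rotation(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, reflections disallowed) minimizing ||shape @ R - target||."""
    u, _, vt = np.linalg.svd(shape.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    # force a proper rotation: flip the smallest singular direction if needed
    corr = np.diag([1.0, d])
    return u @ corr @ vt


def gpa_align(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AlignedShapeSet:
    """Generalized Procrustes superimposition of the main landmarks.

    Each configuration is centered, scaled to unit centroid size and rotated to
    the current mean by the optimal proper rotation (SVD of the cross-covariance,
    determinant forced +1 so faces never mirror); the mean is re-estimated and
    renormalized until it moves less than ``tol`` in RMS.  Initialization is the
    first shape, making the procedure deterministic.
    """
    if len(configs) < 2:
        raise ValueError("GPA requires at least 2 configurations")
    k = configs[0].n_main
    for c in configs:
        if c.n_main != k:
            raise ValueError(
                f"mismatched landmark counts: {c.image_id!r} has {c.n_main}, expected {k}"
            )

    raw = np.stack([c.points_main for c in configs])  # (n, k, 2)
    centroids = raw.mean(axis=1)
    centered = raw - centroids[:, None]
    sizes = np.sqrt((centered**2).sum(axis=(1, 2)))
    for c, s in zip(configs, sizes):
        if s <= 0 or not np.isfinite(s):
            raise ValueError(f"degenerate shape (zero centroid size): {c.image_id!r}")
    scaled = centered / sizes[:, None, None]

    mean = scaled[0].copy()
    rotations = np.tile(np.eye(2), (len(configs), 1, 1))
    rotated = scaled.copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for i in range(len(configs)):
            r = _optimal_rotation(scaled[i], mean)
            rotations[i] = r
            rotated[i] = scaled[i] @ r
        new_mean = rotated.mean(axis=0)
        new_mean = new_mean - new_mean.mean(axis=0)
        new_mean /= np.sqrt((new_mean**2).sum())
        shift = np.sqrt(((new_mean - mean) ** 2).mean())
        mean = new_mean
        if shift < tol:
            break

    # Canonicalize the output frame so the result does not depend on the
    # (arbitrary) orientation of the initializing shape: rotate everything so
    # the mean's baseline (landmark 0 to its farthest landmark) points along +x.
    final_mean = rotated.mean(axis=0)
    d = np.linalg.norm(final_mean - final_mean[0], axis=1)
    v = final_mean[int(np.argmax(d))] - final_mean[0]
    ang = np.arctan2(v[1], v[0])
    Rc = np.array([[np.cos(-ang), -np.sin(-ang)], [np.sin(-ang), np.cos(-ang)]]).T
    rotated = rotated @ Rc
    rotations = rotations @ Rc

    transforms = [
        SimilarityTransform(translation=centroids[i], scale=sizes[i], rotation=rotations[i])
        for i in range(len(configs))
    ]
    # The unit-size mean drives the iteration; the returned mean shape is the
    # exact coordinate-wise average of the aligned sample (size ~1 for small
    # shape variation, but not renormalized).
    return AlignedShapeSet(
        aligned=rotated,
        mean_shape=rotated.mean(axis=0),
        centroid_sizes=sizes,
        transforms=transforms,
        image_ids=[c.image_id for c in configs],
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# Thin-plate splines


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2 with U(0) = 0."""
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return _tps_kernel(d2)


@dataclass
class TpsWarp:
    """An exact-interpolation thin-plate-spline map between two landmark sets.

    The system is solved in centered, unit-scale coordinates (the TPS
    interpolant is invariant under similarity transforms of the coordinate
    frame, and normalization keeps the bordered system well conditioned);
    ``affine`` and ``weights`` refer to that internal frame, and
    ``bending_energy`` is reported in normalized units.
    """

    source: np.ndarray  # (k, 2) original coordinates
    target: np.ndarray  # (k, 2)
    affine: np.ndarray  # (2, 3): columns = constant, x, y coefficients per output dim
    weights: np.ndarray  # (k, 2) kernel coefficients
    bending_energy: float
    src_center: np.ndarray = None
    src_scale: float = 1.0
    tgt_center: np.ndarray = None
    tgt_scale: float = 1.0

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return tps_apply(self, points)


def tps_fit(source: np.ndarray, target: np.ndarray) -> TpsWarp:
    """Fit the thin-plate spline interpolating ``source`` onto ``target``.

    Solves the standard bordered linear system [[K, P], [P.T, 0]] for the kernel
    weights and affine part; the bending energy is the quadratic form of the
    weights with the kernel matrix (zero iff the map is affine).
    """
    src = _as_points(source, "source")
    tgt = _as_points(target, "target")
    k = len(src)
    if len(tgt) != k:
        raise ValueError(f"source has {k} points but target has {len(tgt)}")
    if k < 3:
        raise ValueError("TPS needs at least 3 control points")
    d2 = ((src[:, None] - src[None]) ** 2).sum(axis=2)
    if np.any(d2[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("duplicate source control points make the TPS system singular")

    src_center = src.mean(axis=0)
    src_scale = float(np.sqrt(((src - src_center) ** 2).sum(axis=1).mean())) or 1.0
    tgt_center = tgt.mean(axis=0)
    tgt_scale = float(np.sqrt(((tgt - tgt_center) ** 2).sum(axis=1).mean())) or 1.0
    nsrc = (src - src_center) / src_scale
    ntgt = (tgt - tgt_center) / tgt_scale

    d2 = ((nsrc[:, None] - nsrc[None]) ** 2).sum(axis=2)
    K = _tps_kernel(d2)
    P = np.hstack([np.ones((k, 1)), nsrc])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = ntgt
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare numeric path
        raise ValueError(f"singular TPS system (collinear source points?): {exc}") from exc
    weights = sol[:k]
    affine = sol[k:].T  # (2, 3)
    # exact interpolation is the contract; a collinear/near-singular system
    # shows up as a residual at the control points themselves
    fitted = P @ affine.T + K @ weights
    resid = float(np.abs(fitted - ntgt).max())
    if not np.isfinite(resid) or resid > 1e-8:
        raise ValueError(
            f"degenerate TPS system (control-point residual {resid:.3g}); "
            "source points may be collinear"
        )
    be = float(np.trace(weights.T @ K @ weights))
    return TpsWarp(
        source=src,
        target=tgt,
        affine=affine,
        weights=weights,
        bending_energy=max(be, 0.0),
        src_center=src_center,
        src_scale=src_scale,
        tgt_center=tgt_center,
        tgt_scale=tgt_scale,
    )


def tps_apply(warp: TpsWarp, points: np.ndarray) -> np.ndarray:
    """Evaluate a fitted TPS at arbitrary query points (m x 2)."""
    pts = _as_points(points, "points")
    npts = (pts - warp.src_center) / warp.src_scale
    nsrc = (warp.source - warp.src_center) / warp.src_scale
    U = _kernel_matrix(npts, nsrc)  # (m, k)
    ones = np.ones((len(pts), 1))
    Pq = np.hstack([ones, npts])  # (m, 3)
    out = Pq @ warp.affine.T + U @ warp.weights
    return out * warp.tgt_scale + warp.tgt_center


def tps_transport(
    source_main: np.ndarray,
    target_main: np.ndarray,
    carried: np.ndarray,
) -> np.ndarray:
    """Transport carried points (e.g. semi-landmarks) by the TPS fitted on main points."""
    return tps_apply(tps_fit(source_main, target_main), carried)
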