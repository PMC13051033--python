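"""Multivariate regression of aligned face shape on an impression score.

The model regresses every Procrustes-aligned coordinate on a single centered
impression score (one model per trait and per face sex).  The slope field is a
displacement per unit score; morph targets at +/-k SD of the score are the mean
shape displaced along that field.  Significance of the variance explained is
assessed by permuting scores across faces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .shape_core import (
    AlignedShapeSet,
    LandmarkConfiguration,
    SimilarityTransform,
    tps_transport,
)

__all__ = [
    "TRAITS",
    "ImpressionLabel",
    "ShapeRegressionModel",
    "fit_shape_regression",
    "permutation_test",
    "predict_mean_morph",
    "morph_target_for_face",
    "DEFAULT_MORPH_LEVELS",
]

TRAITS = ("attractiveness", "dominance", "sexual_dimorphism")
RATER_GROUPS = ("all", "male", "female")

#: morph levels in units of the score SD
DEFAULT_MORPH_LEVELS = (-3.0, -1.5, 0.0, 1.5, 3.0)


@dataclass(frozen=True)
class ImpressionLabel:
    """Mean impression score of one image on the 1-7 rating scale."""

    image_id: str
    trait: str
    score: float
    rater_group: str = "all"

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}; expected one of {TRAITS}")
        if self.rater_group not in RATER_GROUPS:
            raise ValueError(f"unknown rater_group {self.rater_group!r}")
        if not 1.0 <= self.score <= 7.0:
            raise ValueError(f"score {self.score} outside the 1-7 scale")


@dataclass
class ShapeRegressionModel:
    """Shape-on-score regression: mean shape, slope field and fit statistics."""

    trait: str
    sex_of_faces: str
    mean_shape: np.ndarray  # (k, 2)
    slopes: np.ndarray  # (k, 2) displacement per unit score
    score_mean: float
    score_sd: float  # population convention (divisor n)
    ss_total: float
    ss_model: float
    n_faces: int
    permutation_p: float | None = None
    n_perm: int = 0

    @property
    def variance_explained_pct(self) -> float:
        return 100.0 * self.ss_model / self.ss_total

    def to_json(self, path) -> None:
        d = {
            "trait": self.trait,
            "sex_of_faces": self.sex_of_faces,
            "mean_shape": self.mean_shape.ravel().tolist(),
            "slopes": self.slopes.ravel().tolist(),
            "score_mean": self.score_mean,
            "score_sd": self.score_sd,
            "ss_total": self.ss_total,
            "ss_model": self.ss_model,
            "n_faces": self.n_faces,
            "permutation_p": self.permutation_p,
            "n_perm": self.n_perm,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ShapeRegressionModel":
        with open(path) as fh:
            d = json.load(fh)
        k = len(d["mean_shape"]) // 2
        d["mean_shape"] = np.asarray(d["mean_shape"], dtype=float).reshape(k, 2)
        d["slopes"] = np.asarray(d["slopes"], dtype=float).reshape(k, 2)
        return cls(**d)


def _scores_for(aligned: AlignedShapeSet, labels: list[ImpressionLabel]) -> np.ndarray:
    by_id: dict[str, float] = {}
    for lab in labels:
        if lab.image_id in by_id:
            raise ValueError(f"duplicate label for image {lab.image_id!r}")
        by_id[lab.image_id] = lab.score
    missing = [i for i in aligned.image_ids if i not in by_id]
    if missing:
        raise ValueError(f"missing labels for images: {missing}")
    return np.array([by_id[i] for i in aligned.image_ids], dtype=float)


def _fit_stats(resid_flat: np.ndarray, s_centered: np.ndarray):
    """OLS of each coordinate on the centered score. Returns (slopes, ss_model, ss_total)."""
    ssx = float(s_centered @ s_centered)
    slopes = (s_centered @ resid_flat) / ssx  # (2k,)
    ss_model = float((slopes**2).sum() * ssx)
    ss_total = float((resid_flat**2).sum())
    return slopes, ss_model, ss_total


def fit_shape_regression(
    aligned: AlignedShapeSet,
    labels: list[ImpressionLabel],
    trait: str | None = None,
    sex_of_faces: str = "all",
) -> ShapeRegressionModel:
    """Ordinary least squares of each aligned coordinate on the centered score.

    ``ss_model`` is the regression sum of squares summed over the 2k coordinates
    and ``ss_total`` the total Procrustes sum of squares about the mean shape,
    so ``variance_explained_pct`` is the share of Procrustes variance the score
    accounts for.
    """
    if aligned.n_shapes < 3:
        raise ValueError("shape regression needs at least 3 faces")
    scores = _scores_for(aligned, labels)
    if np.var(scores) == 0:
        raise ValueError("score variance is zero; cannot regress shape on score")
    trait = trait or labels[0].trait
    k = aligned.mean_shape.shape[0]
    resid = aligned.residuals.reshape(aligned.n_shapes, 2 * k)
    s = scores - scores.mean()
    slopes, ss_model, ss_total = _fit_stats(resid, s)
    return ShapeRegressionModel(
        trait=trait,
        sex_of_faces=sex_of_faces,
        mean_shape=aligned.mean_shape.copy(),
        slopes=slopes.reshape(k, 2),
        score_mean=float(scores.mean()),
        score_sd=float(scores.std()),  # divisor n
        ss_total=ss_total,
        ss_model=ss_model,
        n_faces=aligned.n_shapes,
    )


def permutation_test(
    aligned: AlignedShapeSet,
    labels: list[ImpressionLabel],
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for the variance explained by the shape regression.

    Scores are permuted across faces and the model refitted for each draw;
    p = (1 + #{permuted >= observed}) / (1 + n_perm), the add-one convention
    that keeps p strictly positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = _scores_for(aligned, labels)
    if np.var(scores) == 0:
        raise ValueError("score variance is zero")
    k = aligned.mean_shape.shape[0]
    resid = aligned.residuals.reshape(aligned.n_shapes, 2 * k)
    s = scores - scores.mean()
    ssx = float(s @ s)
    observed = ((s @ resid) ** 2).sum() / ssx  # ss_model for the observed labels

    # permuting s leaves ssx unchanged; ss_model = ||resid.T @ s_perm||^2 / ssx
    perms = np.empty((n_perm, len(s)))
    for i in range(n_perm):
        perms[i] = rng.permutation(s)
    ss_perm = ((perms @ resid) ** 2).sum(axis=1) / ssx
    n_ge = int((ss_perm >= observed).sum())
    return (1 + n_ge) / (1 + n_perm)


def predict_mean_morph(model: ShapeRegressionModel, level_sd: float) -> LandmarkConfiguration:
    """Mean shape displaced by ``level_sd`` score SDs along the slope field.

    Returned in the aligned (Procrustes) frame; level 0 is the mean shape exactly.
    """
    if not np.isfinite(level_sd):
        raise ValueError("level_sd must be finite")
    pts = model.mean_shape + model.slopes * (level_sd * model.score_sd)
    return LandmarkConfiguration(
        points_main=pts, image_id=f"mean_morph_{model.trait}_{level_sd:+g}sd"
    )


def morph_target_for_face(
    model: ShapeRegressionModel,
    face_aligned: np.ndarray,
    transform: SimilarityTransform,
    level_sd: float,
    semi_image_space: np.ndarray | None = None,
) -> LandmarkConfiguration:
    """Morph target for one face, mapped back into that face's own pixel frame.

    The displacement ``slopes * level_sd * score_sd`` is added in the aligned
    frame, then the face's stored inverse Procrustes transform returns it to
    image space.  Semi-landmarks (given in image space) are transported by the
    TPS fitted on the main landmarks.
    """
    if transform is None:
        raise ValueError("face has no stored Procrustes back-transform")
    face_aligned = np.asarray(face_aligned, dtype=float)
    target_aligned = face_aligned + model.slopes * (level_sd * model.score_sd)
    target_image = transform.to_image(target_aligned)
    source_image = transform.to_image(face_aligned)
    if semi_image_space is not None and len(semi_image_space):
        semi_target = tps_transport(source_image, target_image, semi_image_space)
    else:
        semi_target = np.empty((0, 2))
    return LandmarkConfiguration(
        points_main=target_image,
        points_semi=semi_target,
        image_id=f"morph_{model.trait}_{level_sd:+g}sd",
    )
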