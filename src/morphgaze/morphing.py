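"""Dense TPS image warping, oval clipping and average-face compositing.

Warping uses backward mapping: a TPS is fitted from the *target* landmarks to
the *source* landmarks, evaluated at every output pixel center, and the source
image is bilinearly sampled there.  Eight stationary anchor points (the image
corners and edge midpoints) are appended to the control points so the picture
edges do not collapse when the face deforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .shape_core import LandmarkConfiguration, tps_fit, tps_apply
from .impression import (
    ShapeRegressionModel,
    morph_target_for_face,
    DEFAULT_MORPH_LEVELS,
)

__all__ = [
    "FaceImage",
    "MorphedStimulus",
    "warp_image",
    "oval_clip",
    "average_faces",
    "make_stimuli",
    "DEFAULT_BACKGROUND",
]

#: mid-grey background used outside the face oval and for out-of-source samples
DEFAULT_BACKGROUND = (128, 128, 128)


@dataclass
class FaceImage:
    """An 8-bit RGB raster plus its landmark configuration."""

    pixels: np.ndarray  # (H, W, 3) uint8
    image_id: str
    landmarks: LandmarkConfiguration

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got {px.shape}")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class MorphedStimulus:
    base_image_id: str
    trait: str
    level_sd: float
    image: FaceImage

    @property
    def stimulus_id(self) -> str:
        return f"{self.base_image_id}_{self.trait}_{self.level_sd:+g}sd"


def _anchor_points(h: int, w: int) -> np.ndarray:
    """Image corners + edge midpoints, kept stationary during dense warps."""
    return np.array(
        [
            [0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1],
            [(w - 1) / 2, 0], [(w - 1) / 2, h - 1],
            [0, (h - 1) / 2], [w - 1, (h - 1) / 2],
        ],
        dtype=float,
    )


def warp_image(
    image: FaceImage,
    target_landmarks: LandmarkConfiguration,
    background=DEFAULT_BACKGROUND,
    add_anchors: bool = True,
) -> FaceImage:
    """Warp ``image`` so its landmarks move onto ``target_landmarks``.

    Main and semi landmarks are used jointly as TPS control points.  Returns a
    raster of the same size with the target landmarks attached.
    """
    src_pts = image.landmarks.all_points
    tgt_pts = target_landmarks.all_points
    if len(src_pts) != len(tgt_pts):
        raise ValueError(
            f"control point mismatch: source {len(src_pts)} vs target {len(tgt_pts)}"
        )
    h, w = image.shape
    if add_anchors:
        anchors = _anchor_points(h, w)
        src_pts = np.vstack([src_pts, anchors])
        tgt_pts = np.vstack([tgt_pts, anchors])

    warp = tps_fit(tgt_pts, src_pts)  # backward map: output pixel -> source pixel
    ys, xs = np.mgrid[0:h, 0:w]
    grid = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src_xy = tps_apply(warp, grid)
    coords = np.stack([src_xy[:, 1].reshape(h, w), src_xy[:, 0].reshape(h, w)])  # (row, col)

    # pixel-area convention: samples within half a pixel of the border take the
    # edge value; only genuinely out-of-source samples get the background fill
    inside = (
        (coords[0] > -0.5) & (coords[0] < h - 0.5) & (coords[1] > -0.5) & (coords[1] < w - 0.5)
    )
    out = np.empty((h, w, 3), dtype=np.uint8)
    for c in range(3):
        ch = ndimage.map_coordinates(
            image.pixels[:, :, c].astype(float), coords, order=1, mode="nearest"
        )
        ch[~inside] = float(background[c])
        out[:, :, c] = np.clip(np.rint(ch), 0, 255).astype(np.uint8)
    return FaceImage(pixels=out, image_id=image.image_id, landmarks=target_landmarks)


def oval_mask(
    shape: tuple[int, int], landmarks: LandmarkConfiguration, padding: float = 0.05
) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipse fitted to the main-landmark bbox."""
    h, w = shape
    pts = landmarks.points_main
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    center = (lo + hi) / 2
    semi = (hi - lo) / 2 * (1 + padding)
    ys, xs = np.mgrid[0:h, 0:w]
    return ((xs - center[0]) / semi[0]) ** 2 + ((ys - center[1]) / semi[1]) ** 2 <= 1.0


def oval_clip(
    image: FaceImage, padding: float = 0.05, background=DEFAULT_BACKGROUND
) -> FaceImage:
    """Set pixels outside the face oval to a uniform background."""
    mask = oval_mask(image.shape, image.landmarks, padding)
    out = np.empty_like(image.pixels)
    out[:] = np.asarray(background, dtype=np.uint8)
    out[mask] = image.pixels[mask]
    return FaceImage(pixels=out, image_id=image.image_id, landmarks=image.landmarks)


def average_faces(
    images: list[FaceImage],
    reference: LandmarkConfiguration,
    background=DEFAULT_BACKGROUND,
) -> FaceImage:
    """Warp every image onto the reference shape and average the pixels."""
    if not images:
        raise ValueError("average_faces needs at least one image")
    acc = np.zeros((*images[0].shape, 3), dtype=float)
    for img in images:
        acc += warp_image(img, reference, background=background).pixels
    mean = np.clip(np.rint(acc / len(images)), 0, 255).astype(np.uint8)
    return FaceImage(pixels=mean, image_id="composite", landmarks=reference)


def make_stimuli(
    images: list[FaceImage],
    aligned_index: dict[str, int],
    aligned_set,
    models: dict[str, ShapeRegressionModel],
    levels=DEFAULT_MORPH_LEVELS,
    clip: bool = True,
    background=DEFAULT_BACKGROUND,
) -> list[MorphedStimulus]:
    """Produce the full stimulus grid: every base image at every trait and level.

    ``aligned_index`` maps image_id to its row in ``aligned_set`` (the GPA result
    the models were fitted on).  Yields |images| x |models| x |levels| stimuli
    with unique (base, trait, level) keys.
    """
    out: list[MorphedStimulus] = []
    for img in images:
        idx = aligned_index[img.image_id]
        face_aligned = aligned_set.aligned[idx]
        transform = aligned_set.transforms[idx]
        for trait, model in models.items():
            for level in levels:
                target = morph_target_for_face(
                    model,
                    face_aligned,
                    transform,
                    level,
                    semi_image_space=img.landmarks.points_semi,
                )
                warped = warp_image(img, target, background=background)
                if clip:
                    warped = oval_clip(warped, background=background)
                out.append(
                    MorphedStimulus(
                        base_image_id=img.image_id,
                        trait=trait,
                        level_sd=float(level),
                        image=warped,
                    )
                )
    return out
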