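"""Synthetic face worlds with known ground truth.

Every stage of the pipeline is exercised on data from this module: landmark
populations whose shape carries a known score-linked displacement, schematic
face images rendered deterministically from the landmarks (so appearance
encodes exactly the shape signal), 7-point ratings drawn from a known linear
mixed model, and gaze sample streams built from AOI-weighted fixation mixtures
with saccade jumps and blink gaps.  A truth ledger records every latent used,
sufficient to compute the expected value of every estimator in the pipeline.

Faces are schematic rather than photorealistic: the pipeline's mathematics is
appearance-agnostic, and schematic rendering makes localization ground truth
exact.  The default experimental design mirrors a typical face-impression
study: 35 raters (16 male, 19 female), 240 trials each over 3 traits x 5 morph
levels, balanced image sexes, 5000 ms of viewing per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .shape_core import LandmarkConfiguration
from .gaze import TrialRecord, FixationEvent, SEX_CODES
from .morphing import FaceImage

__all__ = [
    "FaceTemplate",
    "SyntheticWorldConfig",
    "make_template",
    "default_beta",
    "sample_population",
    "render_face",
    "make_design",
    "simulate_ratings",
    "simulate_gaze",
    "template_aoi_points",
]


# ---------------------------------------------------------------------------
# template


@dataclass
class FaceTemplate:
    """Schematic, bilaterally symmetric face of 52 main + 87 semi landmarks.

    Coordinates live in the unit box (x right, y down, face centered at
    x = 0.5).  ``groups`` indexes the main landmarks by feature; ``contours``
    lists each drawable feature's outline as ordered (is_semi, index) pairs;
    ``mirror_permutation`` maps each main landmark to its bilateral partner.
    """

    points_main: np.ndarray
    points_semi: np.ndarray
    groups: dict
    contours: dict
    mirror_permutation: np.ndarray

    def configuration(self, image_id: str = "template") -> LandmarkConfiguration:
        return LandmarkConfiguration(
            points_main=self.points_main.copy(),
            points_semi=self.points_semi.copy(),
            image_id=image_id,
        )

    def feature_polygon(self, name: str, main: np.ndarray, semi: np.ndarray) -> np.ndarray:
        """Ordered contour of a feature for an arbitrary deformed configuration."""
        return np.array(
            [semi[i] if is_semi else main[i] for is_semi, i in self.contours[name]]
        )


def _mirror(pts: np.ndarray) -> np.ndarray:
    out = pts.copy()
    out[:, 0] = 1.0 - out[:, 0]
    return out


def _interp_contour(pts: np.ndarray, n: int, closed: bool = False) -> np.ndarray:
    """n points evenly spaced in arc length along the polyline through pts."""
    p = np.vstack([pts, pts[:1]]) if closed else pts
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # incommensurate offset so semis never land exactly on main points
    # (a half-step offset would hit the opposite landmark of symmetric contours)
    tq = (np.arange(n) + 0.37) / n * s[-1]
    x = np.interp(tq, s, p[:, 0])
    y = np.interp(tq, s, p[:, 1])
    return np.column_stack([x, y])


def make_template() -> FaceTemplate:
    """Deterministic schematic face: outline, eyes, eyebrows, nose, mouth.

    52 main landmarks (13 jaw outline, 2x5 eyebrows, 2x6 eyes, 7 nose,
    10 mouth) and 87 semi-landmarks interpolated along the same contours.
    """
    # jaw outline: 13 points from left temple, around the chin, to right temple
    # (y grows downward, so sin > 0 is the lower half of the ellipse)
    t = np.linspace(np.pi, 0.0, 13)
    cx, cy = 0.5, 0.48
    ax_, ay_ = 0.30, 0.36
    jaw = np.column_stack([cx + ax_ * np.cos(t), cy + ay_ * np.sin(t)])

    brow_l = np.array(
        [[0.26, 0.355], [0.30, 0.335], [0.345, 0.330], [0.39, 0.340], [0.425, 0.360]]
    )
    brow_r = _mirror(brow_l)[::-1]

    eye_l = np.array(
        [[0.28, 0.435], [0.315, 0.415], [0.355, 0.415], [0.39, 0.435],
         [0.355, 0.455], [0.315, 0.455]]
    )
    eye_r = _mirror(eye_l)[::-1]

    nose = np.array(
        [[0.5, 0.45], [0.47, 0.54], [0.53, 0.54], [0.44, 0.585], [0.56, 0.585],
         [0.5, 0.575], [0.5, 0.61]]
    )
    mouth = np.array(
        [[0.40, 0.70], [0.45, 0.675], [0.50, 0.685], [0.55, 0.675], [0.60, 0.70],
         [0.55, 0.725], [0.50, 0.735], [0.45, 0.725], [0.50, 0.695], [0.50, 0.715]]
    )

    main = np.vstack([jaw, brow_l, brow_r, eye_l, eye_r, nose, mouth])
    groups = {
        "jaw": np.arange(0, 13),
        "eyebrow_left": np.arange(13, 18),
        "eyebrow_right": np.arange(18, 23),
        "eye_left": np.arange(23, 29),
        "eye_right": np.arange(29, 35),
        "nose": np.arange(35, 42),
        "mouth": np.arange(42, 52),
    }

    # mirror permutation: jaw reverses, left/right features swap (reversed order)
    perm = np.empty(52, dtype=int)
    perm[groups["jaw"]] = groups["jaw"][::-1]
    perm[groups["eyebrow_left"]] = groups["eyebrow_right"][::-1]
    perm[groups["eyebrow_right"]] = groups["eyebrow_left"][::-1]
    perm[groups["eye_left"]] = groups["eye_right"][::-1]
    perm[groups["eye_right"]] = groups["eye_left"][::-1]
    perm[groups["nose"]] = [0, 2, 1, 4, 3, 5, 6]
    perm[groups["nose"]] += groups["nose"][0]
    perm[groups["mouth"]] = np.array([4, 3, 2, 1, 0, 7, 6, 5, 8, 9]) + groups["mouth"][0]

    # semi-landmarks: 24 jaw, 2x8 eyebrows, 2x8 eyes, 12 nose, 19 mouth = 87
    semi_parts = {
        "jaw": _interp_contour(jaw, 24),
        "eyebrow_left": _interp_contour(brow_l, 8),
        "eyebrow_right": _interp_contour(brow_r, 8),
        "eye_left": _interp_contour(eye_l, 8, closed=True),
        "eye_right": _interp_contour(eye_r, 8, closed=True),
        "nose": _interp_contour(nose[[0, 1, 3, 6, 4, 2, 0]], 12),
        "mouth": _interp_contour(mouth[:8], 19, closed=True),
    }
    semi = np.vstack(list(semi_parts.values()))
    semi_groups = {}
    off = 0
    for name, pts in semi_parts.items():
        semi_groups[name] = np.arange(off, off + len(pts))
        off += len(pts)

    def contour(name, closed_main_idx, semi_name):
        """Interleave main and semi points by angular/arc order around the feature."""
        m_idx = groups[name] if closed_main_idx is None else closed_main_idx
        pts = [(False, int(i)) for i in m_idx] + [(True, int(i)) for i in semi_groups[semi_name]]
        coords = np.array([semi[i] if s else main[i] for s, i in pts])
        center = coords.mean(axis=0)
        ang = np.arctan2(coords[:, 1] - center[1], coords[:, 0] - center[0])
        order = np.argsort(ang)
        return [pts[i] for i in order]

    contours = {
        "eye_left": contour("eye_left", None, "eye_left"),
        "eye_right": contour("eye_right", None, "eye_right"),
        "mouth": contour("mouth", groups["mouth"][:8], "mouth"),
        # open contours drawn as thick polylines
        "eyebrow_left": [(False, int(i)) for i in groups["eyebrow_left"]],
        "eyebrow_right": [(False, int(i)) for i in groups["eyebrow_right"]],
        "jaw": [(False, int(i)) for i in groups["jaw"]],
        "nose": [(False, int(i)) for i in groups["nose"][[1, 3, 6, 4, 2]]],
    }
    return FaceTemplate(
        points_main=main,
        points_semi=semi,
        groups=groups,
        contours=contours,
        mirror_permutation=perm,
    )


def similarity_basis(points: np.ndarray) -> np.ndarray:
    """Orthonormal basis (4 x 2k) of the similarity subspace at a configuration:
    x/y translation, scaling and infinitesimal rotation."""
    k = len(points)
    c = points - points.mean(axis=0)
    basis = np.zeros((4, 2 * k))
    basis[0, 0::2] = 1.0
    basis[1, 1::2] = 1.0
    basis[2] = c.ravel()
    rot = np.column_stack([-c[:, 1], c[:, 0]])
    basis[3] = rot.ravel()
    q, _ = np.linalg.qr(basis.T)
    return q.T


def default_beta(
    template: FaceTemplate,
    feature: str = "eyebrows",
    magnitude: float = 0.012,
    pure_shape: bool = True,
) -> np.ndarray:
    """Score-linked displacement field (52 x 2) per unit score.

    The default raises the eyebrows with the score, the kind of localized
    shape-impression link reported for dominance-like traits.  With
    ``pure_shape=True`` the field is projected off the similarity subspace at
    the template (translation, scale, rotation), so it is a genuine shape
    change that Procrustes superimposition cannot absorb; set it False to keep
    the displacement strictly inside the feature (useful when rendered-image
    localization ground truth must be exact).
    """
    beta = np.zeros((52, 2))
    if feature == "eyebrows":
        idx = np.concatenate([template.groups["eyebrow_left"], template.groups["eyebrow_right"]])
        beta[idx, 1] = -magnitude  # upward (y grows downward)
    elif feature in template.groups:
        beta[template.groups[feature], 1] = -magnitude
    else:
        raise ValueError(f"unknown feature {feature!r}")
    if pure_shape:
        q = similarity_basis(template.points_main)
        flat = beta.ravel()
        beta = (flat - q.T @ (q @ flat)).reshape(52, 2)
    return beta


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SyntheticWorldConfig:
    """All knobs of the synthetic world; every stochastic step is seeded.

    Defaults mirror the emulated study design: 80 base faces, scores on the
    1-7 scale, 35 raters (16 male / 19 female) x 240 trials, 5000 ms viewing,
    video eye-tracker sampling at 1000 Hz with ~35 px per degree of visual
    angle.
    """

    seed: int = 0
    n_faces: int = 80
    score_mean: float = 3.5
    score_sd: float = 0.7
    beta_feature: str = "eyebrows"
    beta_magnitude: float = 0.012  # unit-box displacement per unit score
    beta_pure_shape: bool = True  # project the field off translation/scale/rotation
    landmark_noise_sd: float | None = None  # default: 10% of per-coordinate signal SD
    render_size: int = 256

    # rating model
    rating_grand_mean: float = 4.0
    slope_morph: float = 0.12  # per SD morph level
    image_sex_effect: float = 0.14
    participant_sex_effect: float = 0.0
    interaction_effects: dict = field(default_factory=dict)  # term -> effect
    participant_intercept_sd: float = 0.5
    stimulus_intercept_sd: float = 0.3
    residual_sd: float = 1.0
    n_participants_male: int = 16
    n_participants_female: int = 19
    n_trials_per_participant: int = 240

    # gaze model
    sampling_rate: float = 1000.0  # Hz
    px_per_deg: float = 35.0
    viewing_ms: float = 5000.0
    aoi_weights: dict = field(
        default_factory=lambda: {
            "eyes": 0.30, "nose": 0.22, "mouth": 0.16, "eyebrows": 0.10,
            "glabella": 0.08, "cheeks": 0.06, "forehead": 0.04, "chin": 0.04,
        }
    )
    fixation_mean_ms: float = 250.0
    fixation_sd_ms: float = 80.0
    min_fixation_ms: float = 100.0
    saccade_ms: float = 30.0
    blink_prob: float = 0.05  # chance a between-fixation gap is a blink
    blink_ms: float = 150.0
    aoi_scatter_deg: float = 0.6
    min_saccade_amplitude_deg: float = 2.0  # re-fixations below this are not resolvable

    def __post_init__(self) -> None:
        w = sum(self.aoi_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"AOI weights must sum to 1 (got {w})")

    def noise_sd(self, beta: np.ndarray) -> float:
        """Per-coordinate landmark noise SD: 10% of the RMS signal displacement
        at one score SD, unless set explicitly."""
        if self.landmark_noise_sd is not None:
            return self.landmark_noise_sd
        signal_rms = float(np.sqrt((beta**2).mean()))
        return 0.1 * signal_rms * self.score_sd


# ---------------------------------------------------------------------------
# population


def sample_population(
    config: SyntheticWorldConfig,
    template: FaceTemplate | None = None,
    rng: np.random.Generator | None = None,
):
    """Draw a face population with a known score-linked shape displacement.

    score_i ~ Normal(score_mean, score_sd); main landmarks are
    template + score_i * beta + coordinate noise; semi-landmarks ride along by
    the same per-face displacement interpolated at their contour positions
    (the template's semi construction).  Returns (configs, scores, truth).
    """
    template = template or make_template()
    rng = rng or np.random.default_rng(config.seed)
    beta = default_beta(
        template, config.beta_feature, config.beta_magnitude, config.beta_pure_shape
    )
    noise_sd = config.noise_sd(beta)
    scores = np.clip(
        rng.normal(config.score_mean, config.score_sd, config.n_faces), 1.0, 7.0
    )
    configs = []
    for i, s in enumerate(scores):
        disp = s * beta
        noise = rng.normal(0.0, noise_sd, (52, 2))
        main = template.points_main + disp + noise
        # semis follow their feature's mean displacement (smooth transport)
        semi = template.points_semi.copy()
        for name, idx in template.groups.items():
            semi_idx = _semi_groups_cache(template)[_SEMI_NAME_MAP.get(name, name)]
            semi[semi_idx] += disp[idx].mean(axis=0)
        configs.append(
            LandmarkConfiguration(points_main=main, points_semi=semi, image_id=f"face{i:04d}")
        )
    # planned Procrustes variance explained: similarity components of both the
    # signal field and the noise are absorbed by the superimposition
    q = similarity_basis(template.points_main)
    bflat = beta.ravel()
    b_shape = bflat - q.T @ (q @ bflat)
    sig = float(scores.var() * (b_shape**2).sum())
    noi = noise_sd**2 * (104 - 4)
    truth = {
        "beta_true": beta,
        "scores": scores,
        "noise_sd": noise_sd,
        "score_mean": config.score_mean,
        "score_sd": config.score_sd,
        "planned_variance_explained_pct": 100.0 * sig / (sig + noi) if sig + noi else 0.0,
    }
    return configs, scores, truth


_SEMI_NAME_MAP = {}  # feature names coincide between main and semi groups


def _semi_groups_cache(template: FaceTemplate) -> dict:
    # rebuild the semi index layout used by make_template
    sizes = {"jaw": 24, "eyebrow_left": 8, "eyebrow_right": 8, "eye_left": 8,
             "eye_right": 8, "nose": 12, "mouth": 19}
    out = {}
    off = 0
    for name, nn in sizes.items():
        out[name] = np.arange(off, off + nn)
        off += nn
    return out


# ---------------------------------------------------------------------------
# rendering

#: grey levels per feature (uint8); appearance is a pure function of landmarks
FEATURE_SHADE = {
    "skin": 215,
    "jaw_line": 120,
    "eyebrow": 50,
    "eye": 70,
    "nose": 140,
    "mouth": 95,
    "background": 245,
}


def render_face(
    landmarks: LandmarkConfiguration,
    size: int = 256,
    template: FaceTemplate | None = None,
    supersample: int = 4,
) -> FaceImage:
    """Rasterize a schematic face from a (possibly deformed) configuration.

    Features are filled anti-aliased polygons at fixed grey levels on a uniform
    background; identical landmarks give pixel-identical images.
    """
    template = template or make_template()
    main = np.asarray(landmarks.points_main, dtype=float)
    semi = np.asarray(landmarks.points_semi, dtype=float)
    if np.any(main < 0) or np.any(main > 1):
        raise ValueError("landmarks outside the unit canvas; rescale before rendering")
    S = size * supersample
    img = Image.new("L", (S, S), FEATURE_SHADE["background"])
    drw = ImageDraw.Draw(img)

    def px(pts):
        return [(float(p[0]) * S, float(p[1]) * S) for p in np.atleast_2d(pts)]

    lw = max(1, S // 128)
    # face disc: smooth closed curve through the jaw + a forehead arc
    # forehead apex follows the jaw geometry only, so feature-local shape
    # signals (e.g. eyebrow displacement) never move the head outline
    jaw_pts = template.feature_polygon("jaw", main, semi)
    temple_y = min(jaw_pts[0, 1], jaw_pts[-1, 1])
    top = np.array([[jaw_pts[:, 0].mean(), max(temple_y - 0.34, 0.02)]])
    left_temple, right_temple = jaw_pts[0], jaw_pts[-1]
    forehead = np.array(
        [left_temple * 0.4 + top[0] * 0.6 + [-0.03, 0.0], top[0],
         right_temple * 0.4 + top[0] * 0.6 + [0.03, 0.0]]
    )
    face_poly = np.vstack([jaw_pts, forehead[::-1]])
    drw.polygon(px(face_poly), fill=FEATURE_SHADE["skin"])
    drw.line(px(jaw_pts), fill=FEATURE_SHADE["jaw_line"], width=lw)

    for name in ("eyebrow_left", "eyebrow_right"):
        drw.line(px(template.feature_polygon(name, main, semi)),
                 fill=FEATURE_SHADE["eyebrow"], width=3 * lw)
    for name in ("eye_left", "eye_right"):
        drw.polygon(px(template.feature_polygon(name, main, semi)), fill=FEATURE_SHADE["eye"])
    drw.line(px(template.feature_polygon("nose", main, semi)),
             fill=FEATURE_SHADE["nose"], width=2 * lw)
    drw.polygon(px(template.feature_polygon("mouth", main, semi)), fill=FEATURE_SHADE["mouth"])

    img = img.resize((size, size), Image.BILINEAR)
    px_scale = float(size)
    cfg = LandmarkConfiguration(
        points_main=main * px_scale,
        points_semi=semi * px_scale if len(semi) else semi,
        image_id=landmarks.image_id,
    )
    arr = np.asarray(img, dtype=np.uint8)
    return FaceImage(pixels=np.stack([arr] * 3, axis=-1), image_id=landmarks.image_id, landmarks=cfg)


# ---------------------------------------------------------------------------
# AOI geometry


def template_aoi_points(template: FaceTemplate | None = None) -> dict:
    """Named AOI point groups (unit coordinates) derived from the template.

    eyes/eyebrows/nose/mouth come straight from the landmark groups; glabella,
    cheeks, chin and forehead are derived geometrically.
    """
    template = template or make_template()
    m = template.points_main
    g = template.groups
    eyes = m[np.concatenate([g["eye_left"], g["eye_right"]])]
    brows = m[np.concatenate([g["eyebrow_left"], g["eyebrow_right"]])]
    inner_l = m[g["eyebrow_left"]][-1]
    inner_r = m[g["eyebrow_right"]][0]
    glabella = np.array(
        [inner_l, inner_r, (inner_l + inner_r) / 2 + [0, 0.04], (inner_l + inner_r) / 2 - [0, 0.02]]
    )
    nose = m[g["nose"]]
    mouth = m[g["mouth"]]
    eye_out_l = m[g["eye_left"]][0]
    eye_out_r = m[g["eye_right"]][-1]
    mouth_l, mouth_r = mouth[0], mouth[4]
    cheeks = np.array(
        [eye_out_l + [0.0, 0.06], eye_out_l + [-0.02, 0.14], mouth_l + [-0.06, -0.04],
         eye_out_r + [0.0, 0.06], eye_out_r + [0.02, 0.14], mouth_r + [0.06, -0.04]]
    )
    jaw = m[g["jaw"]]
    chin = jaw[5:8]  # bottom of the outline
    forehead = brows.copy()
    forehead[:, 1] -= 0.10
    return {
        "eyes": eyes, "eyebrows": brows, "glabella": glabella, "nose": nose,
        "mouth": mouth, "cheeks": cheeks, "chin": chin, "forehead": forehead,
    }


# ---------------------------------------------------------------------------
# ratings


def make_design(config: SyntheticWorldConfig, traits=("attractiveness", "dominance", "sexual_dimorphism"),
                levels=(-3.0, -1.5, 0.0, 1.5, 3.0)) -> pd.DataFrame:
    """Participant x trial design table: who rates which stimulus on which trait.

    Stimuli are balanced over image sex and morph level; each participant sees
    ``n_trials_per_participant`` trials split evenly over traits.
    """
    participants = [
        (f"p{i:03d}", "male") for i in range(config.n_participants_male)
    ] + [
        (f"p{i + config.n_participants_male:03d}", "female")
        for i in range(config.n_participants_female)
    ]
    per_trait = config.n_trials_per_participant // len(traits)
    rows = []
    rng = np.random.default_rng(config.seed + 7)
    n_stim = max(config.n_faces, 2)
    for pid, psex in participants:
        for trait in traits:
            stim_ids = rng.permutation(n_stim)[:per_trait] if per_trait <= n_stim else rng.integers(0, n_stim, per_trait)
            for j, sid in enumerate(stim_ids):
                level = levels[(j + sid) % len(levels)]
                image_sex = "male" if sid % 2 == 0 else "female"
                rows.append(
                    {
                        "participant_id": pid, "participant_sex": psex,
                        "stimulus_id": f"s{sid:04d}", "image_sex": image_sex,
                        "trait": trait, "level_sd": float(level),
                    }
                )
    return pd.DataFrame(rows)


def simulate_ratings(design: pd.DataFrame, config: SyntheticWorldConfig,
                     rng: np.random.Generator | None = None):
    """Draw 1-7 ratings from the known mixed model.

    rating = grand mean + slope_morph*level + image-sex and participant-sex
    effects (-0.5/+0.5 coding) + interactions + participant intercept +
    stimulus intercept + Normal(0, residual_sd), rounded and clipped to 1..7.
    Returns (DataFrame with a rating column, truth ledger).
    """
    rng = rng or np.random.default_rng(config.seed + 11)
    df = design.copy()
    pids = df["participant_id"].unique()
    sids = df["stimulus_id"].unique()
    u_p = dict(zip(pids, rng.normal(0.0, config.participant_intercept_sd, len(pids))))
    u_s = dict(zip(sids, rng.normal(0.0, config.stimulus_intercept_sd, len(sids))))
    morph = df["level_sd"].to_numpy()
    isx = df["image_sex"].map(SEX_CODES).to_numpy()
    psx = df["participant_sex"].map(SEX_CODES).to_numpy()
    ix = config.interaction_effects
    mu = (
        config.rating_grand_mean
        + config.slope_morph * morph
        + config.image_sex_effect * isx
        + config.participant_sex_effect * psx
        + ix.get("morph:image_sex", 0.0) * morph * isx
        + ix.get("morph:participant_sex", 0.0) * morph * psx
        + ix.get("image_sex:participant_sex", 0.0) * isx * psx
        + ix.get("morph:image_sex:participant_sex", 0.0) * morph * isx * psx
        + df["participant_id"].map(u_p).to_numpy()
        + df["stimulus_id"].map(u_s).to_numpy()
    )
    latent = mu + rng.normal(0.0, config.residual_sd, len(df))
    df["rating"] = np.clip(np.rint(latent), 1, 7).astype(int)
    truth = {
        "grand_mean": config.rating_grand_mean,
        "slope_morph": config.slope_morph,
        "image_sex_effect": config.image_sex_effect,
        "participant_sex_effect": config.participant_sex_effect,
        "interaction_effects": dict(ix),
        "participant_intercepts": u_p,
        "stimulus_intercepts": u_s,
        "residual_sd": config.residual_sd,
    }
    return df, truth


# ---------------------------------------------------------------------------
# gaze


def simulate_gaze(
    config: SyntheticWorldConfig,
    aoi_centers: dict,
    screen: tuple[int, int],
    rng: np.random.Generator,
    aoi_weights: dict | None = None,
):
    """One trial's gaze sample stream over the viewing window.

    Alternates fixations (target AOI ~ categorical(weights), position Gaussian
    around the AOI center, duration truncated-normal) with short high-velocity
    saccade segments; occasional gaps are emitted as invalid (blink) runs.
    Returns (DataFrame[t_ms, x_px, y_px, valid], truth) where truth counts the
    emitted fixations and their AOI assignments.
    """
    weights = aoi_weights or config.aoi_weights
    names = list(weights)
    wvec = np.array([weights[n] for n in names])
    wvec = wvec / wvec.sum()
    dt = 1000.0 / config.sampling_rate
    h, w = screen
    scatter_px = config.aoi_scatter_deg * config.px_per_deg

    t = 0.0
    rows = []
    fix_truth = []
    pos = None
    min_amp_px = config.min_saccade_amplitude_deg * config.px_per_deg
    while t < config.viewing_ms:
        aoi = names[rng.choice(len(names), p=wvec)]
        center = np.asarray(aoi_centers[aoi], dtype=float)
        new_pos = center + rng.normal(0.0, scatter_px, 2)
        new_pos = np.clip(new_pos, [0, 0], [w - 1, h - 1])
        if pos is not None and np.linalg.norm(new_pos - pos) < min_amp_px:
            # a hop below the saccade amplitude floor is not a separable event:
            # the eye keeps fixating; extend the ongoing fixation in place
            emitted = 0
            dur = max(rng.normal(config.fixation_mean_ms, config.fixation_sd_ms),
                      config.min_fixation_ms)
            for _ in range(int(round(dur / dt))):
                if t >= config.viewing_ms:
                    break
                jit = rng.normal(0.0, 0.15, 2)
                rows.append((t, pos[0] + jit[0], pos[1] + jit[1], 1))
                t += dt
                emitted += 1
            if fix_truth and emitted:
                fix_truth[-1]["duration_ms"] += emitted * dt
            continue
        if pos is not None:
            # transit: saccade, occasionally replaced by a blink gap
            if rng.random() < config.blink_prob:
                n_gap = max(2, int(round(config.blink_ms / dt)))
                for _ in range(n_gap):
                    if t >= config.viewing_ms:
                        break
                    rows.append((t, np.nan, np.nan, 0))
                    t += dt
            else:
                n_sac = max(2, int(round(config.saccade_ms / dt)))
                for k in range(n_sac):
                    if t >= config.viewing_ms:
                        break
                    frac = (k + 1) / (n_sac + 1)
                    p = pos + (new_pos - pos) * frac
                    rows.append((t, p[0], p[1], 1))
                    t += dt
        dur = rng.normal(config.fixation_mean_ms, config.fixation_sd_ms)
        dur = max(dur, config.min_fixation_ms)
        n_fix = int(round(dur / dt))
        emitted = 0
        for _ in range(n_fix):
            if t >= config.viewing_ms:
                break
            jit = rng.normal(0.0, 0.15, 2)
            rows.append((t, new_pos[0] + jit[0], new_pos[1] + jit[1], 1))
            t += dt
            emitted += 1
        if emitted * dt >= config.min_fixation_ms:
            fix_truth.append({"aoi": aoi, "x": new_pos[0], "y": new_pos[1],
                              "duration_ms": emitted * dt})
        pos = new_pos

    df = pd.DataFrame(rows, columns=["t_ms", "x_px", "y_px", "valid"])
    truth = {"n_fixations": len(fix_truth), "fixations": fix_truth}
    return df, truth


def trials_from_design(
    rated: pd.DataFrame,
    fixations_by_row: list | None = None,
) -> list[TrialRecord]:
    """Convert a rated design table (plus optional fixation lists) to TrialRecords."""
    out = []
    for i, r in enumerate(rated.itertuples()):
        fx = fixations_by_row[i] if fixations_by_row is not None else []
        out.append(
            TrialRecord(
                participant_id=r.participant_id,
                participant_sex=r.participant_sex,
                stimulus_id=r.stimulus_id,
                image_sex=r.image_sex,
                trait=r.trait,
                level_sd=r.level_sd,
                rating=int(r.rating),
                fixations=[fx_ if isinstance(fx_, FixationEvent) else FixationEvent(**fx_) for fx_ in fx],
            )
        )
    return out
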