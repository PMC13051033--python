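"""Eye-tracking analytics: event parsing, fixation maps, pixel statistics and
the rating mixed model.

Gaze samples are parsed into blinks (invalid runs), saccades (velocity above
30 deg/s or acceleration above 8000 deg/s^2) and fixations (everything else,
subject to a minimum duration); the three classes partition the trace.
Fixation maps are duration-weighted, Gaussian-smoothed spatial histograms.
Condition contrasts are computed per pixel as a paired within-participant
difference with a one-sample t-test across participants and Benjamini-Hochberg
FDR across pixels.  Ratings are modelled by a Gaussian linear mixed model with
crossed random intercepts for participants and stimuli, fitted by profiled
restricted maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "EventParserSettings",
    "FixationEvent",
    "SaccadeEvent",
    "BlinkEvent",
    "TrialRecord",
    "FixationMap",
    "PixelStatMap",
    "RatingModelResult",
    "parse_events",
    "fixation_map",
    "pixelwise_contrast",
    "fdr_adjust",
    "fit_rating_lmm",
]

SEX_CODES = {"male": -0.5, "female": 0.5}


@dataclass
class EventParserSettings:
    """Thresholds for classifying gaze samples into oculomotor events.

    Velocity/acceleration thresholds follow the standard video eye-tracker
    parser (30 deg/s, 8000 deg/s^2).  ``px_per_deg`` converts pixel distances
    to degrees of visual angle.
    """

    sampling_rate: float  # Hz
    px_per_deg: float
    velocity_thresh: float = 30.0  # deg/s
    accel_thresh: float = 8000.0  # deg/s^2
    min_fixation_ms: float = 50.0

    def __post_init__(self) -> None:
        for name in ("sampling_rate", "px_per_deg", "velocity_thresh", "accel_thresh", "min_fixation_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class FixationEvent:
    t_start: float  # ms
    t_end: float
    x: float  # px, duration-weighted centroid
    y: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class SaccadeEvent:
    t_start: float
    t_end: float


@dataclass(frozen=True)
class BlinkEvent:
    t_start: float
    t_end: float


@dataclass
class TrialRecord:
    """One experimental trial: who saw what, the rating given, and the gaze."""

    participant_id: str
    participant_sex: str
    stimulus_id: str
    image_sex: str
    trait: str
    level_sd: float
    rating: int
    fixations: list[FixationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.rating <= 7:
            raise ValueError(f"rating {self.rating} outside the 1-7 scale")
        if self.participant_sex not in SEX_CODES or self.image_sex not in SEX_CODES:
            raise ValueError("sex must be 'male' or 'female'")


@dataclass
class FixationMap:
    grid: np.ndarray  # (H, W) non-negative, ms-weighted
    condition: dict = field(default_factory=dict)
    smoothing_sigma_px: float = 0.0


@dataclass
class PixelStatMap:
    beta: np.ndarray  # (H, W) signed contrast
    p: np.ndarray  # (H, W)
    sig_mask: np.ndarray  # (H, W) bool, after FDR
    n_participants: int = 0


def _runs(labels: np.ndarray):
    """Yield (label, start_idx, stop_idx_exclusive) for contiguous runs."""
    if len(labels) == 0:
        return
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(labels)]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        yield labels[a], a, b


def parse_events(t_ms, x_px, y_px, valid, settings: EventParserSettings):
    """Classify a time-ordered gaze sample stream into fixations, saccades, blinks.

    Blinks are maximal runs of invalid samples.  Within each valid run, velocity
    is computed by central differences (the two-sample span doubles as the
    smoothing window) and acceleration from that velocity; samples exceeding
    either threshold are saccade samples.  Remaining runs of at least
    ``min_fixation_ms`` become fixations (centroid = mean position); shorter
    residual runs are absorbed into the saccade class so the three classes
    partition the trace.

    Returns ``(fixations, saccades, blinks, labels)`` where ``labels`` marks
    every sample 0=blink, 1=saccade, 2=fixation.
    """
    t = np.asarray(t_ms, dtype=float)
    x = np.asarray(x_px, dtype=float)
    y = np.asarray(y_px, dtype=float)
    v = np.asarray(valid).astype(bool)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    dt_ms = 1000.0 / settings.sampling_rate

    BLINK, SACC, FIX = 0, 1, 2
    labels = np.full(len(t), FIX, dtype=int)
    labels[~v] = BLINK

    for lab, a, b in _runs(v.astype(int)):
        if lab == 0 or b - a < 3:
            continue
        ts, xs, ys = t[a:b], x[a:b], y[a:b]
        # central-difference velocity in deg/s; the two-sample span is itself
        # the smoothing (keeps event boundaries within one sample of a jump)
        vel = np.empty(b - a)
        dpos = np.hypot(xs[2:] - xs[:-2], ys[2:] - ys[:-2])
        vel[1:-1] = dpos / (ts[2:] - ts[:-2]) * 1000.0 / settings.px_per_deg
        vel[0] = vel[1]
        vel[-1] = vel[-2]
        acc = np.zeros_like(vel)
        acc[1:-1] = (vel[2:] - vel[:-2]) / (ts[2:] - ts[:-2]) * 1000.0
        sacc = (vel > settings.velocity_thresh) | (np.abs(acc) > settings.accel_thresh)
        labels[a:b][sacc] = SACC

    # residual valid runs shorter than the fixation floor join the saccade class
    for lab, a, b in _runs(labels):
        if lab == FIX and (b - a) * dt_ms < settings.min_fixation_ms:
            labels[a:b] = SACC

    fixations, saccades, blinks = [], [], []
    for lab, a, b in _runs(labels):
        t0 = float(t[a])
        t1 = float(t[b - 1] + dt_ms)
        if lab == FIX:
            fixations.append(
                FixationEvent(t_start=t0, t_end=t1, x=float(x[a:b].mean()), y=float(y[a:b].mean()))
            )
        elif lab == SACC:
            saccades.append(SaccadeEvent(t_start=t0, t_end=t1))
        else:
            blinks.append(BlinkEvent(t_start=t0, t_end=t1))
    return fixations, saccades, blinks, labels


def fixation_map(
    trials: list[TrialRecord],
    shape: tuple[int, int],
    smoothing_sigma_px: float,
    condition: dict | None = None,
) -> FixationMap:
    """Duration-weighted fixation heatmap for a set of trials.

    Each fixation deposits its duration (ms) at its centroid pixel; the summed
    grid is convolved with an isotropic Gaussian.  Total mass before smoothing
    equals the summed durations; truncation at the image border is the only
    mass loss.
    """
    h, w = shape
    grid = np.zeros((h, w))
    if not trials:
        warnings.warn("empty condition: returning a zero fixation map")
        return FixationMap(grid=grid, condition=condition or {}, smoothing_sigma_px=smoothing_sigma_px)
    for tr in trials:
        for fx in tr.fixations:
            c = int(round(fx.x))
            r = int(round(fx.y))
            if 0 <= r < h and 0 <= c < w:
                grid[r, c] += fx.duration
    if smoothing_sigma_px > 0:
        grid = ndimage.gaussian_filter(grid, smoothing_sigma_px, mode="constant")
    return FixationMap(grid=grid, condition=condition or {}, smoothing_sigma_px=smoothing_sigma_px)


def fdr_adjust(pvals, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean rejection mask in the input order."""
    p = np.asarray(pvals, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(ranked <= thresh)
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask


def pixelwise_contrast(
    trials: list[TrialRecord],
    shape: tuple[int, int],
    smoothing_sigma_px: float,
    positive_levels=(1.5, 3.0),
    negative_levels=(-1.5, -3.0),
    q: float = 0.05,
) -> PixelStatMap:
    """Pixel-wise morph-condition contrast on smoothed fixation-duration maps.

    Within each participant, the mean map over positive-level trials minus the
    mean map over negative-level trials is formed; per pixel, a one-sample
    two-tailed t-test across participants tests that paired difference against
    zero, and Benjamini-Hochberg FDR at ``q`` is applied across pixels.  Sign
    convention: beta > 0 where gaze mass is larger in the positive condition.
    """
    pos, neg = set(positive_levels), set(negative_levels)
    by_part: dict[str, dict[str, list[TrialRecord]]] = {}
    for tr in trials:
        cell = "pos" if tr.level_sd in pos else "neg" if tr.level_sd in neg else None
        if cell is None:
            continue
        by_part.setdefault(tr.participant_id, {"pos": [], "neg": []})[cell].append(tr)

    diffs = []
    for pid, cells in sorted(by_part.items()):
        if not cells["pos"] or not cells["neg"]:
            warnings.warn(f"participant {pid!r} observed in only one contrast cell; dropped")
            continue
        mp = fixation_map(cells["pos"], shape, smoothing_sigma_px).grid / len(cells["pos"])
        mn = fixation_map(cells["neg"], shape, smoothing_sigma_px).grid / len(cells["neg"])
        diffs.append(mp - mn)
    if len(diffs) < 2:
        raise ValueError("pixelwise contrast needs >= 2 participants with both cells")

    d = np.stack(diffs)  # (P, H, W)
    P = d.shape[0]
    mean_d = d.mean(axis=0)
    sd_d = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = mean_d / (sd_d / np.sqrt(P))
    pmap = 2.0 * stats.t.sf(np.abs(tmap), df=P - 1)
    pmap[~np.isfinite(tmap)] = 1.0  # constant pixels carry no evidence
    pmap = np.clip(pmap, np.finfo(float).tiny, 1.0)
    mask = fdr_adjust(pmap.ravel(), q).reshape(shape)
    return PixelStatMap(beta=mean_d, p=pmap, sig_mask=mask, n_participants=P)


# ---------------------------------------------------------------------------
# Rating linear mixed model (crossed random intercepts, profiled REML)

FIXED_TERMS = (
    "intercept",
    "morph",
    "image_sex",
    "participant_sex",
    "morph:image_sex",
    "morph:participant_sex",
    "image_sex:participant_sex",
    "morph:image_sex:participant_sex",
)


@dataclass
class RatingModelResult:
    """REML fit of rating ~ morph * image_sex * participant_sex + (1|participant) + (1|stimulus)."""

    fixed_effects: dict  # term -> (estimate, std_error, t)
    random_intercept_sd: dict  # {"participant": sd, "stimulus": sd}
    residual_sd: float
    n_obs: int
    converged: bool
    singular: bool
    coding_note: str = "sex dummies: -0.5 male, +0.5 female; morph in SD levels"

    def estimate(self, term: str) -> float:
        return self.fixed_effects[term][0]

    def se(self, term: str) -> float:
        return self.fixed_effects[term][1]


def _design(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build (X, y, participant_idx, stimulus_idx) from TrialRecords or a DataFrame."""
    import pandas as pd

    if isinstance(trials, pd.DataFrame):
        df = trials
    else:
        df = pd.DataFrame(
            {
                "participant_id": [t.participant_id for t in trials],
                "participant_sex": [t.participant_sex for t in trials],
                "stimulus_id": [t.stimulus_id for t in trials],
                "image_sex": [t.image_sex for t in trials],
                "level_sd": [t.level_sd for t in trials],
                "rating": [t.rating for t in trials],
            }
        )
    morph = df["level_sd"].to_numpy(dtype=float)
    isx = df["image_sex"].map(SEX_CODES).to_numpy(dtype=float)
    psx = df["participant_sex"].map(SEX_CODES).to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(df)),
            morph,
            isx,
            psx,
            morph * isx,
            morph * psx,
            isx * psx,
            morph * isx * psx,
        ]
    )
    y = df["rating"].to_numpy(dtype=float)
    pidx = df["participant_id"].astype("category").cat.codes.to_numpy()
    sidx = df["stimulus_id"].astype("category").cat.codes.to_numpy()
    return X, y, pidx, sidx


def fit_rating_lmm(trials) -> RatingModelResult:
    """Fit the rating mixed model by profiled restricted maximum likelihood.

    The model is ``rating ~ morph * image_sex * participant_sex`` with crossed
    random intercepts for participants and stimuli and Gaussian residuals.
    Fixed effects and the residual variance are profiled out analytically (via
    the Woodbury identity on the marginal covariance), leaving a 2-parameter
    optimization over the two variance ratios.  Reports estimate/SE/t per fixed
    term; no denominator-df p-values are attached (t statistics only).
    """
    X, y, pidx, sidx = _design(trials)
    n, p = X.shape
    a = int(pidx.max()) + 1
    b = int(sidx.max()) + 1
    if a < 2 or b < 2:
        raise ValueError("need >= 2 participants and >= 2 stimuli")
    if n <= p:
        raise ValueError("too few observations for the factorial fixed effects")

    if np.var(y) == 0.0:
        fe = {t: (0.0, np.nan, np.nan) for t in FIXED_TERMS}
        fe["intercept"] = (float(y[0]), np.nan, np.nan)
        return RatingModelResult(
            fixed_effects=fe,
            random_intercept_sd={"participant": 0.0, "stimulus": 0.0},
            residual_sd=0.0,
            n_obs=n,
            converged=True,
            singular=True,
        )

    q = a + b
    # sufficient statistics with Z = [participant indicators | stimulus indicators]
    ZtZ = np.zeros((q, q))
    np.add.at(ZtZ, (pidx, pidx), 1.0)
    np.add.at(ZtZ, (a + sidx, a + sidx), 1.0)
    cross = np.zeros((a, b))
    np.add.at(cross, (pidx, sidx), 1.0)
    ZtZ[:a, a:] = cross
    ZtZ[a:, :a] = cross.T
    ZtX = np.zeros((q, p))
    np.add.at(ZtX, pidx, X)
    np.add.at(ZtX, a + sidx, X)
    Zty = np.zeros(q)
    np.add.at(Zty, pidx, y)
    np.add.at(Zty, a + sidx, y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def profile(log_theta):
        th = np.exp(np.clip(log_theta, -30.0, 10.0))
        wvec = np.sqrt(np.concatenate([np.full(a, th[0]), np.full(b, th[1])]))
        A = np.eye(q) + (wvec[:, None] * ZtZ) * wvec[None, :]
        cA = cho_factor(A, lower=True)
        Bx = wvec[:, None] * ZtX
        by = wvec * Zty
        AiBx = cho_solve(cA, Bx)
        Aiby = cho_solve(cA, by)
        XtVinvX = XtX - Bx.T @ AiBx
        XtVinvy = Xty - Bx.T @ Aiby
        ytVinvy = yty - by @ Aiby
        cX = cho_factor(XtVinvX, lower=True)
        beta = cho_solve(cX, XtVinvy)
        rVr = max(ytVinvy - beta @ XtVinvy, 1e-12)
        sigma2 = rVr / (n - p)
        logdetA = 2.0 * np.log(np.diag(cA[0])).sum()
        logdetXVX = 2.0 * np.log(np.diag(cX[0])).sum()
        reml = (n - p) * np.log(sigma2) + logdetA + logdetXVX
        return reml, beta, sigma2, XtVinvX

    res = optimize.minimize(
        lambda lt: profile(lt)[0],
        x0=np.log([0.25, 0.25]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
    )
    theta = np.exp(np.clip(res.x, -30.0, 10.0))
    _, beta, sigma2, XtVinvX = profile(res.x)
    cov = sigma2 * np.linalg.inv(XtVinvX)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    fixed = {term: (float(beta[i]), float(se[i]), float(tstat[i])) for i, term in enumerate(FIXED_TERMS)}
    singular = bool(np.any(theta < 1e-8))
    return RatingModelResult(
        fixed_effects=fixed,
        random_intercept_sd={
            "participant": float(np.sqrt(theta[0] * sigma2)),
            "stimulus": float(np.sqrt(theta[1] * sigma2)),
        },
        residual_sd=float(np.sqrt(sigma2)),
        n_obs=n,
        converged=bool(res.success),
        singular=singular,
    )
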