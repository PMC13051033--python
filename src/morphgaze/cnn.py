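"""A compact NumPy regression CNN with Grad-CAM attention extraction.

The scorer is a six-convolution network: 3x3 convolutions each followed by
batch normalization and ReLU, a 2x2 max-pool after every second convolution,
and a single linear output unit on the flattened features.  Training is
mini-batch Adam on mean-squared error with a fixed epoch schedule.  Forward
and backward passes are written directly in NumPy (im2col convolutions), which
keeps inference deterministic and gives Grad-CAM exact access to the gradient
of the scalar output with respect to the final convolutional feature maps.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize
from scipy import stats

from .gaze import fdr_adjust

__all__ = [
    "CnnConfig",
    "TrainedScorer",
    "CvReport",
    "AttentionMap",
    "build_scorer",
    "train",
    "fine_tune",
    "predict",
    "cross_validate",
    "gradcam",
    "attention_significance",
]


@dataclass
class CnnConfig:
    input_size: tuple[int, int, int] = (96, 96, 3)  # (H, W, channels)
    conv_filters: tuple[int, ...] = (32, 32, 64, 64, 128, 128)
    kernel_size: int = 3
    pool_every: int = 2
    lr: float = 0.001
    batch_size: int = 16
    epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 6:
            raise ValueError("the scorer uses exactly 6 convolutional layers")
        h, w, _ = self.input_size
        n_pools = len(self.conv_filters) // self.pool_every
        if h % (2**n_pools) or w % (2**n_pools):
            raise ValueError(
                f"input {h}x{w} not divisible by 2^{n_pools} pooling stages"
            )


# ---------------------------------------------------------------------------
# layers (NCHW, float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patch matrix, same padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h * w, c * k * k)


def _col2im(dcols: np.ndarray, shape, k: int) -> np.ndarray:
    n, c, h, w = shape
    p = k // 2
    dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcols.dtype)
    d = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, :, :, i, j]
    return dxp[:, :, p : p + h, p : p + w]


class _Conv:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.W = (rng.standard_normal((c_out, c_in * k * k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    def forward(self, x, train):
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        n, c, h, w = x.shape
        out = self._cols @ self.W.T + self.b
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, co, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n, h * w, co)
        self.dW = np.einsum("npk,npc->ck", self._cols, dflat, optimize=True)
        self.db = dflat.sum(axis=(0, 1))
        dcols = dflat @ self.W
        self._cols = None
        return _col2im(dcols, self._shape, self.k)

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


class _BatchNorm:
    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        self._xhat = (x - mean[None, :, None, None]) * self._istd[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * self._istd[None, :, None, None]
        self._xhat = None
        return dx

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def grads(self):
        return [self.dgamma, self.dbeta]


class _ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


class _MaxPool2:
    def forward(self, x, train):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        return out

    def backward(self, dout):
        d = dout[:, :, :, None, :, None] * self._mask
        n, c, h2, _, w2, _ = d.shape
        self._mask = None
        return d.reshape(n, c, h2 * 2, w2 * 2)

    def params(self):
        return []

    def grads(self):
        return []


class _Dense:
    # The scalar readout starts at zero: weight then accumulates only on
    # features whose gradient correlates with the label, so label-irrelevant
    # activations never acquire readout weight (which would otherwise leak
    # arbitrary init noise into gradient-based attribution maps).
    def __init__(self, d_in: int, rng: np.random.Generator):
        self.W = np.zeros((d_in, 1), dtype=np.float32)
        self.b = np.zeros(1, dtype=np.float32)

    def forward(self, x, train):
        self._shape = x.shape
        self._flat = x.reshape(x.shape[0], -1)
        return (self._flat @ self.W + self.b).ravel()

    def backward(self, dout):
        dout = dout.reshape(-1, 1).astype(np.float32)
        self.dW = self._flat.T @ dout
        self.db = dout.sum(axis=0)
        dx = (dout @ self.W.T).reshape(self._shape)
        self._flat = None
        return dx

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return [self.dW, self.db]


@dataclass
class TrainedScorer:
    """A (possibly trained) scorer: layer stack, config and training provenance."""

    config: CnnConfig
    layers: list
    history: list = field(default_factory=list)  # per-epoch mean MSE
    provenance: dict = field(default_factory=dict)
    #: index of the final convolution's ReLU output in the layer stack
    cam_layer: int = 0

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for lay in self.layers for _, p in lay.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def clone(self) -> "TrainedScorer":
        return copy.deepcopy(self)


def build_scorer(config: CnnConfig) -> TrainedScorer:
    """Assemble the six-conv regression network with seeded weight init."""
    rng = np.random.default_rng(config.seed)
    h, w, c_in = config.input_size
    layers: list = []
    c_prev = c_in
    hh, ww = h, w
    cam_layer = 0
    for i, c_out in enumerate(config.conv_filters):
        layers.append(_Conv(c_prev, c_out, config.kernel_size, rng))
        layers.append(_BatchNorm(c_out))
        layers.append(_ReLU())
        if i == len(config.conv_filters) - 1:
            cam_layer = len(layers) - 1  # final conv block's ReLU output
        if (i + 1) % config.pool_every == 0:
            layers.append(_MaxPool2())
            hh //= 2
            ww //= 2
        c_prev = c_out
    layers.append(_Dense(hh * ww * c_prev, rng))
    return TrainedScorer(config=config, layers=layers, cam_layer=cam_layer)


def _prepare(images: np.ndarray, config: CnnConfig) -> np.ndarray:
    """uint8 (N, H, W, 3) -> float32 NCHW in [-0.5, 0.5]."""
    x = np.asarray(images)
    if x.ndim == 3:
        x = x[None]
    h, w, c = config.input_size
    if x.shape[1:] != (h, w, c):
        raise ValueError(f"images have shape {x.shape[1:]}, model expects {(h, w, c)}")
    return (x.astype(np.float32) / 255.0 - 0.5).transpose(0, 3, 1, 2)


class _Adam:
    def __init__(self, params, lr):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float32)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + eps)


def train(
    model: TrainedScorer,
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int | None = None,
    verbose: bool = False,
) -> TrainedScorer:
    """Seeded, shuffled mini-batch training on mean-squared error (no early stop)."""
    config = model.config
    y = np.asarray(labels, dtype=np.float32)
    x = _prepare(images, config)
    n = len(x)
    if n < 1:
        raise ValueError("no training images")
    epochs = config.epochs if epochs is None else epochs
    rng = np.random.default_rng(config.seed + 1)
    params = [p for lay in model.layers for _, p in lay.params()]
    opt = _Adam(params, config.lr)
    bs = min(config.batch_size, n)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            pred = model.forward(x[idx], train=True)
            err = pred - y[idx]
            loss = float((err**2).mean())
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // bs}; "
                    "check label scale and learning rate"
                )
            losses.append(loss)
            dout = (2.0 / len(idx)) * err
            grad = dout
            for lay in reversed(model.layers):
                grad = lay.backward(grad)
            opt.step([g for lay in model.layers for g in lay.grads()])
        model.history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs} mse={model.history[-1]:.5f}")
    model.provenance.setdefault("role", "base")
    model.provenance["epochs_trained"] = model.provenance.get("epochs_trained", 0) + epochs
    return model


def predict(model: TrainedScorer, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Deterministic inference (batch-norm uses running statistics)."""
    x = _prepare(images, model.config)
    out = []
    for start in range(0, len(x), batch_size):
        out.append(model.forward(x[start : start + batch_size], train=False))
    return np.concatenate(out)


def fine_tune(
    base: TrainedScorer,
    images: np.ndarray,
    labels: np.ndarray,
    rater_group: str = "all",
    epochs: int | None = None,
) -> TrainedScorer:
    """Continue training all layers of a copy of ``base`` on new labels.

    Nothing is frozen; the returned scorer records its fine-tuning provenance.
    """
    if not base.history:
        raise ValueError("fine_tune expects a trained base model")
    model = base.clone()
    model.provenance = dict(base.provenance, role="fine-tuned", rater_group=rater_group)
    return train(model, images, labels, epochs=epochs)


@dataclass
class CvReport:
    fold_r: list
    fold_p: list
    fold_flags: list  # "ok" or "constant-predictions"
    folds: list  # index arrays
    mean_r: float


def cross_validate(
    images: np.ndarray,
    labels: np.ndarray,
    config: CnnConfig,
    k: int = 5,
    epochs: int | None = None,
    seed: int | None = None,
) -> CvReport:
    """Seeded k-fold cross-validation scored by the Pearson correlation
    between held-out predictions and labels (two-tailed p per fold)."""
    y = np.asarray(labels, dtype=float)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} items, got {n}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    folds = np.array_split(rng.permutation(n), k)
    rs, ps, flags = [], [], []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        model = build_scorer(
            CnnConfig(**{**config.__dict__, "seed": config.seed + fi})
        )
        train(model, images[train_idx], y[train_idx], epochs=epochs)
        pred = predict(model, images[test_idx])
        if np.std(pred) == 0 or np.std(y[test_idx]) == 0:
            rs.append(0.0)
            ps.append(1.0)
            flags.append("constant-predictions")
        else:
            r, p = stats.pearsonr(pred, y[test_idx])
            rs.append(float(r))
            ps.append(float(p))
            flags.append("ok")
    return CvReport(
        fold_r=rs, fold_p=ps, fold_flags=flags, folds=[f.tolist() for f in folds],
        mean_r=float(np.mean(rs)),
    )


@dataclass
class AttentionMap:
    grid: np.ndarray  # (H, W) non-negative
    source: dict = field(default_factory=dict)

    @property
    def scale_0_255(self) -> np.ndarray:
        """Min-max scaled rendering view; statistics always use ``grid``."""
        g = self.grid
        rng = g.max() - g.min()
        if rng == 0:
            return np.zeros_like(g, dtype=np.uint8)
        return np.clip(np.rint((g - g.min()) / rng * 255), 0, 255).astype(np.uint8)


def gradcam(
    model: TrainedScorer,
    image: np.ndarray,
    source: dict | None = None,
    sign: str = "auto",
) -> AttentionMap:
    """Grad-CAM for the scalar regression output.

    Channel weights are the spatial means of d(output)/d(activation) at the
    final convolution's ReLU output; the map is the rectified weighted sum of
    those activations, bilinearly upsampled to the input size.  Adding a
    constant to the model output leaves the map unchanged.

    Unlike a class logit, a regression output has no privileged gradient
    direction: evidence can lower the score as legitimately as raise it, and
    rectifying the raw weighted sum can discard the informative side entirely.
    ``sign='auto'`` (default) therefore rectifies the side of the
    gradient-weighted field carrying the larger energy; ``sign='positive'``
    is the classification-style convention.  The two agree whenever the field
    is predominantly positive.
    """
    x = _prepare(image, model.config)
    if x.shape[0] != 1:
        raise ValueError("gradcam expects a single image")
    act = None
    h = x
    for i, lay in enumerate(model.layers):
        h = lay.forward(h, train=False)
        if i == model.cam_layer:
            act = h.copy()
    grad = np.ones(1, dtype=np.float32)
    g = grad
    for i in range(len(model.layers) - 1, model.cam_layer, -1):
        g = model.layers[i].backward(g)
    # g is now d(output)/d(cam activations): (1, C, h, w)
    weights = g.mean(axis=(2, 3))[0]  # (C,)
    field = (weights[:, None, None] * act[0]).sum(axis=0)
    if sign == "auto":
        s = 1.0 if np.maximum(field, 0).sum() >= np.maximum(-field, 0).sum() else -1.0
    elif sign == "positive":
        s = 1.0
    else:
        raise ValueError(f"unknown sign convention {sign!r}")
    cam = np.maximum(s * field, 0.0)
    hh, ww, _ = model.config.input_size
    up = resize(cam.astype(float), (hh, ww), order=1, mode="edge", anti_aliasing=False)
    return AttentionMap(grid=np.maximum(up, 0.0), source=source or {})


def attention_significance(
    maps: list[AttentionMap] | np.ndarray,
    q: float = 0.05,
    tail: str = "greater",
) -> np.ndarray:
    """Per-pixel one-sample t-test of attention maps against zero, BH FDR at q.

    ``tail='greater'`` tests positivity (the default for rectified maps);
    ``tail='two-sided'`` is the variant used for signed difference maps.
    Constant pixels carry no evidence (p = 1).
    """
    grids = np.stack([m.grid if isinstance(m, AttentionMap) else m for m in maps])
    if grids.shape[0] < 2:
        raise ValueError("need >= 2 maps")
    n = grids.shape[0]
    mean = grids.mean(axis=0)
    sd = grids.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    if tail == "greater":
        p = stats.t.sf(t, df=n - 1)
    elif tail == "two-sided":
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p[~np.isfinite(t)] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return fdr_adjust(p.ravel(), q).reshape(mean.shape)
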