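"""Small convolutional classifier, implemented directly on NumPy.

Layer stack: three conv/ReLU/max-pool stages (C1-P2, C3-P4, C5-P6),
dropout (D7), one fully connected ReLU layer (F8), dropout (D9), and a
linear output scored through a softmax with cross-entropy loss. Training
is plain mini-batch SGD with an L2 weight-decay term; dropout is inverted
(scaled at train time) so inference needs no compensation.

All forward/backward passes are hand-written (im2col convolutions), which
keeps the arithmetic inspectable and testable against finite differences.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

# ---------------------------------------------------------------------------
# specs and configs
# ---------------------------------------------------------------------------


@dataclass
class NetworkSpec:
    """Architecture hyperparameters. Defaults follow the 78x78 input
    collapsing to a small spatial grid after three conv/pool stages."""

    n_classes: int = 8
    input_size: int = 78
    in_channels: int = 1
    conv_channels: tuple[int, ...] = (32, 64, 128)
    conv_kernels: tuple[int, ...] = (5, 5, 4)
    pool: int = 2
    fc_units: int = 256
    dropout_p: float = 0.5

    def __post_init__(self):
        if len(self.conv_channels) != len(self.conv_kernels):
            raise ValueError("conv_channels and conv_kernels must align")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    def feature_shape(self) -> tuple[int, int]:
        """(channels, side) after the conv/pool stack."""
        side = self.input_size
        ch = self.in_channels
        for out_ch, k in zip(self.conv_channels, self.conv_kernels):
            side = side - k + 1
            if side <= 0:
                raise ValueError("kernel larger than feature map")
            side = side // self.pool
            ch = out_ch
        return ch, side


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 20
    weight_decay: float = 0.01
    epochs: int = 60
    momentum: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_error: list[float] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    val_error: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# primitive ops
# ---------------------------------------------------------------------------


def softmax(scores: np.ndarray) -> np.ndarray:
    """Shift-invariant softmax along the last axis."""
    q = np.asarray(scores, np.float64)
    shifted = q - q.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, target_onehot: np.ndarray) -> float:
    """Mean -log p(true class), natural log, with a 1e-12 clamp."""
    p = np.clip(np.asarray(probs, np.float64), 1e-12, None)
    t = np.asarray(target_onehot, np.float64)
    per_item = -(t * np.log(p)).sum(axis=-1)
    return float(per_item.mean())


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (B, C, H, W) -> (B, H', W', C*k*k)
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # (B, C, H', W', k, k) -> (B, H', W', C, k, k)
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        x.shape[0], x.shape[2] - k + 1, x.shape[3] - k + 1, -1
    )


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Valid-padding stride-1 correlation. w: (O, C, k, k)."""
    o, c, k, _ = w.shape
    cols = _im2col(x, k)
    out = cols @ w.reshape(o, -1).T + b
    return out.transpose(0, 3, 1, 2), cols


def conv_backward(dout: np.ndarray, cols: np.ndarray, x_shape, w: np.ndarray):
    o, c, k, _ = w.shape
    b_, _, hp, wp = dout.shape
    dr = dout.transpose(0, 2, 3, 1).reshape(-1, o)
    cols_r = cols.reshape(-1, cols.shape[-1])
    dw = (dr.T @ cols_r).reshape(w.shape)
    db = dr.sum(axis=0)
    dcols = (dr @ w.reshape(o, -1)).reshape(b_, hp, wp, c, k, k)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + hp, j : j + wp] += dcols[:, :, :, :, i, j].transpose(
                0, 3, 1, 2
            )
    return dx, dw, db


def maxpool_forward(x: np.ndarray, p: int):
    b, c, h, w = x.shape
    h2, w2 = h // p, w // p
    xc = x[:, :, : h2 * p, : w2 * p]
    blocks = xc.reshape(b, c, h2, p, w2, p)
    out = blocks.max(axis=(3, 5))
    mask = blocks == out[:, :, :, None, :, None]
    counts = mask.sum(axis=(3, 5), keepdims=True)
    return out, (mask, counts, x.shape, p)


def maxpool_backward(dout: np.ndarray, cache):
    mask, counts, x_shape, p = cache
    b, c, h, w = x_shape
    h2, w2 = mask.shape[2], mask.shape[4]
    spread = mask / counts * dout[:, :, :, None, :, None]
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, : h2 * p, : w2 * p] = spread.reshape(b, c, h2 * p, w2 * p)
    return dx


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def init_params(
    spec: NetworkSpec, seed: int = 0, dtype=np.float32
) -> dict[str, np.ndarray]:
    """Seeded scaled-uniform initialization: U(-s, s), s = sqrt(6 / fan_in).

    float32 by default (the heavy matmuls run ~2x faster); pass
    dtype=np.float64 for finite-difference verification work.
    """
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    in_ch = spec.in_channels
    for i, (out_ch, k) in enumerate(zip(spec.conv_channels, spec.conv_kernels), 1):
        fan_in = in_ch * k * k
        s = np.sqrt(6.0 / fan_in)
        params[f"W{i}"] = rng.uniform(-s, s, size=(out_ch, in_ch, k, k)).astype(dtype)
        params[f"b{i}"] = np.zeros(out_ch, dtype)
        in_ch = out_ch
    ch, side = spec.feature_shape()
    flat = ch * side * side
    s = np.sqrt(6.0 / flat)
    params["Wf"] = rng.uniform(-s, s, size=(spec.fc_units, flat)).astype(dtype)
    params["bf"] = np.zeros(spec.fc_units, dtype)
    s = np.sqrt(6.0 / spec.fc_units)
    params["Wo"] = rng.uniform(-s, s, size=(spec.n_classes, spec.fc_units)).astype(dtype)
    params["bo"] = np.zeros(spec.n_classes, dtype)
    return params


def _prepare_input(x: np.ndarray, spec: NetworkSpec, dtype=np.float32) -> np.ndarray:
    x = np.asarray(x, dtype)
    if x.ndim == 3:
        x = x[:, None, :, :]
    if x.shape[1:] != (spec.in_channels, spec.input_size, spec.input_size):
        raise ValueError(
            f"input shape {x.shape[1:]} does not match spec "
            f"({spec.in_channels}, {spec.input_size}, {spec.input_size})"
        )
    if x.max() > 1.5:  # raw grey levels: scale to [0, 1]
        x = x / 255.0
    return x


def forward(
    spec: NetworkSpec,
    params: dict[str, np.ndarray],
    x: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
    return_cache: bool = False,
):
    """Score vectors for a batch. Dropout is active only with train=True
    (requires an rng); evaluation mode is fully deterministic."""
    if train and spec.dropout_p > 0 and rng is None:
        raise ValueError("training-mode forward requires an rng for dropout")
    dtype = params["Wf"].dtype
    x = _prepare_input(x, spec, dtype)
    cache: dict = {"x": x}
    h = x
    for i in range(1, len(spec.conv_channels) + 1):
        z, cols = conv_forward(h, params[f"W{i}"], params[f"b{i}"])
        a = np.maximum(z, 0.0)
        pooled, pcache = maxpool_forward(a, spec.pool)
        cache[f"conv{i}"] = (h.shape, cols, z, pcache)
        h = pooled
    b = h.shape[0]
    flat = h.reshape(b, -1)
    cache["flat_shape"] = h.shape
    if train and spec.dropout_p > 0:
        d7 = ((rng.random(flat.shape) >= spec.dropout_p) / (1 - spec.dropout_p)).astype(dtype)
    else:
        d7 = None
    h7 = flat * d7 if d7 is not None else flat
    zf = h7 @ params["Wf"].T + params["bf"]
    af = np.maximum(zf, 0.0)
    if train and spec.dropout_p > 0:
        d9 = ((rng.random(af.shape) >= spec.dropout_p) / (1 - spec.dropout_p)).astype(dtype)
    else:
        d9 = None
    h9 = af * d9 if d9 is not None else af
    scores = h9 @ params["Wo"].T + params["bo"]
    cache.update(flat=flat, d7=d7, h7=h7, zf=zf, af=af, d9=d9, h9=h9)
    if return_cache:
        return scores, cache
    return scores


def loss_and_grads(
    spec: NetworkSpec,
    params: dict[str, np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    weight_decay: float = 0.0,
    rng: np.random.Generator | None = None,
    train: bool = True,
):
    """Mean cross-entropy + 0.5*wd*||W||^2 and analytic gradients."""
    scores, cache = forward(spec, params, x, train=train, rng=rng, return_cache=True)
    n = scores.shape[0]
    probs = softmax(scores)
    target = one_hot(np.asarray(y), spec.n_classes)
    data_loss = cross_entropy(probs, target)
    reg = 0.0
    grads: dict[str, np.ndarray] = {}

    dscores = ((probs - target) / n).astype(params["Wf"].dtype)
    grads["Wo"] = dscores.T @ cache["h9"]
    grads["bo"] = dscores.sum(axis=0)
    dh9 = dscores @ params["Wo"]
    daf = dh9 * cache["d9"] if cache["d9"] is not None else dh9
    dzf = daf * (cache["zf"] > 0)
    grads["Wf"] = dzf.T @ cache["h7"]
    grads["bf"] = dzf.sum(axis=0)
    dh7 = dzf @ params["Wf"]
    dflat = dh7 * cache["d7"] if cache["d7"] is not None else dh7
    dh = dflat.reshape(cache["flat_shape"])
    for i in range(len(spec.conv_channels), 0, -1):
        x_shape, cols, z, pcache = cache[f"conv{i}"]
        da = maxpool_backward(dh, pcache)
        dz = da * (z > 0)
        dh, dw, db = conv_backward(dz, cols, x_shape, params[f"W{i}"])
        grads[f"W{i}"] = dw
        grads[f"b{i}"] = db
    if weight_decay > 0:
        for key in params:
            if key.startswith("W"):
                reg += 0.5 * weight_decay * float((params[key] ** 2).sum())
                grads[key] = grads[key] + weight_decay * params[key]
    preds = np.argmax(scores, axis=1)
    return data_loss + reg, grads, preds


def train(
    x: np.ndarray,
    y: np.ndarray,
    spec: NetworkSpec,
    config: TrainConfig,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], TrainHistory]:
    """Mini-batch SGD. Per-epoch training error is accumulated from the
    training-mode batch predictions; loss is the mean batch objective.
    Divergence (non-finite loss) aborts, returning the last finite-epoch
    parameters."""
    rng = np.random.default_rng(config.seed)
    params = init_params(spec, seed=config.seed)
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    history = TrainHistory()
    n = len(x)
    y = np.asarray(y, np.int64)
    last_good = {k: v.copy() for k, v in params.items()}
    for _ in range(config.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        n_wrong = 0
        for start in range(0, n, config.batch_size):
            sel = perm[start : start + config.batch_size]
            loss, grads, preds = loss_and_grads(
                spec, params, x[sel], y[sel], config.weight_decay, rng=rng
            )
            if not np.isfinite(loss):
                history.loss.append(float("nan"))
                return last_good, history
            epoch_losses.append(loss)
            n_wrong += int((preds != y[sel]).sum())
            for key in params:
                if config.momentum > 0:
                    velocity[key] = config.momentum * velocity[key] - (
                        config.learning_rate * grads[key]
                    )
                    params[key] += velocity[key]
                else:
                    params[key] -= config.learning_rate * grads[key]
        history.loss.append(float(np.mean(epoch_losses)))
        history.train_error.append(n_wrong / n)
        if x_val is not None:
            preds_val, _ = predict(spec, params, x_val)
            history.val_error.append(float((preds_val != y_val).mean()))
        last_good = {k: v.copy() for k, v in params.items()}
    return params, history


def predict(
    spec: NetworkSpec,
    params: dict[str, np.ndarray],
    x: np.ndarray,
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Labels (argmax, ties to the lowest index) and softmax probabilities."""
    labels, probs = [], []
    for start in range(0, len(x), batch_size):
        scores = forward(spec, params, x[start : start + batch_size], train=False)
        p = softmax(scores)
        labels.append(np.argmax(p, axis=1))
        probs.append(p)
    if not labels:
        return np.zeros(0, np.int64), np.zeros((0, spec.n_classes))
    return np.concatenate(labels), np.concatenate(probs)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

_CKPT_VERSION = 1


def save_checkpoint(path: str | Path, spec: NetworkSpec, params: dict) -> None:
    meta = json.dumps({"version": _CKPT_VERSION, "spec": asdict(spec)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), np.uint8), **params)


def load_checkpoint(path: str | Path) -> tuple[NetworkSpec, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_dict = meta["spec"]
        for key in ("conv_channels", "conv_kernels"):
            spec_dict[key] = tuple(spec_dict[key])
        spec = NetworkSpec(**spec_dict)
        params = {k: data[k] for k in data.files if k != "__meta__"}
    return spec, params
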