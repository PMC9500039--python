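"""LightOCT classifier and training loop, implemented from scratch in numpy.

LightOCT is a deliberately shallow CNN for tomographic slice classification:

    conv(8, 5x5, same) -> ReLU -> 2x2 max-pool (stride 2)
    -> conv(32, 5x5, same) -> ReLU -> flatten
    -> fully-connected(K) -> softmax

trained with SGD + momentum under categorical cross-entropy. Convolutions
are evaluated as im2col reshapes followed by a single BLAS matmul (float32),
which is fast enough for desk-scale experiments on one CPU; gradients for
the convolution input are computed as a same-padded convolution with the
spatially flipped, channel-transposed kernels.

All randomness (weight initialisation, epoch shuffling, label
randomisation) flows through explicit integer seeds, so a (data, config,
seed) triple reproduces a training run bit-for-bit on the same platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .table import DatasetTable


@dataclass
class ModelConfig:
    """Architecture knobs; defaults are the published LightOCT layout."""

    conv1_filters: int = 8
    conv2_filters: int = 32
    kernel_size: int = 5
    input_height: int = 64
    input_width: int = 64
    n_classes: int = 2

    def __post_init__(self) -> None:
        for name in ("conv1_filters", "conv2_filters", "kernel_size",
                     "input_height", "input_width", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"ModelConfig.{name} must be positive")
        if self.n_classes < 2:
            raise ValueError("ModelConfig.n_classes must be >= 2")
        if min(self.input_height, self.input_width) // 2 < self.kernel_size:
            raise ValueError(
                "input smaller than the kernel after pooling: "
                f"{self.input_height}x{self.input_width} with k={self.kernel_size}"
            )

    @property
    def flat_features(self) -> int:
        return (self.input_height // 2) * (self.input_width // 2) * self.conv2_filters

    def parameter_count(self) -> int:
        k2 = self.kernel_size ** 2
        conv1 = self.conv1_filters * k2 * 1 + self.conv1_filters
        conv2 = self.conv2_filters * k2 * self.conv1_filters + self.conv2_filters
        fc = self.flat_features * self.n_classes + self.n_classes
        return conv1 + conv2 + fc


@dataclass
class TrainConfig:
    """Optimisation knobs.

    Defaults are the desk-scale preset used by the analysis scripts (few
    epochs, lr large enough to move a net that only sees a few hundred
    images). ``TrainConfig.full_scale()`` returns the published full-scale
    recipe: lr 1e-4, momentum 0.9, batch 64, 250 epochs, no early stopping.
    """

    learning_rate: float = 0.005
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 8
    seed: int = 0
    loss: str = "categorical_cross_entropy"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("TrainConfig.learning_rate must be > 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("TrainConfig.momentum must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("TrainConfig.epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("TrainConfig.batch_size must be >= 1")
        if self.loss != "categorical_cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "TrainConfig":
        return cls(learning_rate=1e-4, momentum=0.9, batch_size=64,
                   epochs=250, seed=seed)


def _glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Same-padding im2col: (B, H, W, Cin) -> (B*H*W, k*k*Cin) float32 copy.

    Column order is (kh, kw, Cin), matching a (k, k, Cin, Cout) kernel
    reshaped to (k*k*Cin, Cout).
    """
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    bsz, h, wd = x.shape[0], x.shape[1], x.shape[2]
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        bsz * h * wd, -1)


def _conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
               cols: np.ndarray | None = None) -> np.ndarray:
    """Same-padded stride-1 cross-correlation, NHWC.

    x: (B, H, W, Cin); w: (k, k, Cin, Cout). Returns (B, H, W, Cout).
    ``cols`` may supply a precomputed im2col of x.
    """
    k = w.shape[0]
    if cols is None:
        cols = _im2col(x, k)
    wmat = np.ascontiguousarray(w).reshape(k * k * w.shape[2], w.shape[3])
    out = cols @ wmat
    if b is not None:
        out += b
    return out.reshape(x.shape[0], x.shape[1], x.shape[2], -1)


def _conv_backward(x: np.ndarray, w: np.ndarray, dy: np.ndarray,
                   cols: np.ndarray | None = None, need_dx: bool = True):
    """Gradients of a same-padded stride-1 convolution.

    Returns (dx, dw, db). dx is computed as a same-padded convolution of dy
    with the 180-degree-rotated, channel-transposed kernel; ``cols`` may
    supply the im2col of x cached from the forward pass.
    """
    k = w.shape[0]
    bsz, h, wd, cin = x.shape
    cout = w.shape[3]
    if cols is None:
        cols = _im2col(x, k)
    dy_flat = dy.reshape(bsz * h * wd, cout)
    dw = (cols.T @ dy_flat).reshape(k, k, cin, cout)
    db = dy_flat.sum(axis=0)
    if not need_dx:
        return None, dw, db
    w_flip = w[::-1, ::-1].transpose(0, 1, 3, 2)  # (k, k, Cout, Cin)
    dx = _conv_same(dy, np.ascontiguousarray(w_flip), None)
    return dx, dw, db


def _maxpool2(x: np.ndarray):
    """2x2 stride-2 max pool; returns (pooled, argmax) for backprop."""
    bsz, h, wd, c = x.shape
    xr = x[:, : h // 2 * 2, : wd // 2 * 2].reshape(bsz, h // 2, 2, wd // 2, 2, c)
    xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(bsz, h // 2, wd // 2, c, 4)
    arg = xr.argmax(axis=4)
    pooled = np.take_along_axis(xr, arg[..., None], axis=4)[..., 0]
    return pooled, arg


def _maxpool2_backward(dpool: np.ndarray, arg: np.ndarray, in_shape):
    bsz, h, wd, c = in_shape
    d = np.zeros((bsz, h // 2, wd // 2, c, 4), dtype=dpool.dtype)
    np.put_along_axis(d, arg[..., None], dpool[..., None], axis=4)
    d = d.reshape(bsz, h // 2, wd // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return d.reshape(bsz, h // 2 * 2, wd // 2 * 2, c)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class LightOCT:
    """Two-convolutional-layer softmax classifier with explicit parameters.

    Parameters live in ``self.params`` (dict of float32 arrays); training
    history (per-epoch mean loss and validation accuracy) accumulates in
    ``self.history``.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        k, c1, c2 = config.kernel_size, config.conv1_filters, config.conv2_filters
        self.params = {
            "w1": _glorot_uniform(rng, (k, k, 1, c1), k * k * 1, k * k * c1),
            "b1": np.zeros(c1, dtype=np.float32),
            "w2": _glorot_uniform(rng, (k, k, c1, c2), k * k * c1, k * k * c2),
            "b2": np.zeros(c2, dtype=np.float32),
            "w3": _glorot_uniform(rng, (config.flat_features, config.n_classes),
                                  config.flat_features, config.n_classes),
            "b3": np.zeros(config.n_classes, dtype=np.float32),
        }
        self.history: list[dict] = []

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        cfg = self.config
        if images.ndim != 3 or images.shape[1:] != (cfg.input_height, cfg.input_width):
            raise ValueError(
                f"expected images of shape (n, {cfg.input_height}, {cfg.input_width}), "
                f"got {images.shape}"
            )
        return images.astype(np.float32, copy=False)[..., None]

    def _forward(self, x: np.ndarray, cache: bool = False):
        p = self.params
        k = self.config.kernel_size
        cols1 = _im2col(x, k) if cache else None
        z1 = _conv_same(x, p["w1"], p["b1"], cols=cols1)
        a1 = np.maximum(z1, 0.0)
        pool, arg = _maxpool2(a1)
        cols2 = _im2col(pool, k) if cache else None
        z2 = _conv_same(pool, p["w2"], p["b2"], cols=cols2)
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(a2.shape[0], -1)
        logits = flat @ p["w3"] + p["b3"]
        probs = _softmax(logits.astype(np.float64))
        if not cache:
            return probs, None
        return probs, {"x": x, "cols1": cols1, "z1": z1, "a1": a1, "pool": pool,
                       "arg": arg, "cols2": cols2, "z2": z2, "a2": a2, "flat": flat}

    def _backward(self, probs: np.ndarray, onehot: np.ndarray, cache: dict) -> dict:
        p = self.params
        bsz = probs.shape[0]
        dlogits = ((probs - onehot) / bsz).astype(np.float32)
        grads = {
            "w3": cache["flat"].T @ dlogits,
            "b3": dlogits.sum(axis=0),
        }
        dflat = dlogits @ p["w3"].T
        da2 = dflat.reshape(cache["a2"].shape)
        dz2 = da2 * (cache["z2"] > 0)
        dpool, grads["w2"], grads["b2"] = _conv_backward(
            cache["pool"], p["w2"], dz2, cols=cache["cols2"])
        da1 = _maxpool2_backward(dpool, cache["arg"], cache["a1"].shape)
        dz1 = da1 * (cache["z1"] > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(
            cache["x"], p["w1"], dz1, cols=cache["cols1"], need_dx=False)
        return grads

    def predict_probabilities(self, table: DatasetTable) -> np.ndarray:
        """Row-stochastic (n, K) probabilities in ``class_set`` order."""
        x = self._check_input(table.images)
        out = []
        for start in range(0, len(x), 256):
            probs, _ = self._forward(x[start:start + 256])
            out.append(probs)
        return np.concatenate(out) if out else np.zeros((0, self.config.n_classes))


def build_lightoct(config: ModelConfig, seed: int = 0) -> LightOCT:
    """Untrained LightOCT with seeded Glorot-uniform weights."""
    return LightOCT(config, seed=seed)


def train_classifier(model: LightOCT, train: DatasetTable,
                     val: DatasetTable | None, tc: TrainConfig) -> LightOCT:
    """SGD-with-momentum training for exactly ``tc.epochs`` epochs.

    No early stopping; per-epoch shuffling is driven by ``tc.seed``. The
    model is updated in place and returned; ``model.history`` holds one
    entry per epoch with mean training loss and validation accuracy.
    """
    if len(train) == 0:
        raise ValueError("training table is empty")
    if len(train.class_set) != model.config.n_classes:
        raise ValueError(
            f"model expects {model.config.n_classes} classes, dataset has "
            f"{len(train.class_set)}"
        )
    if val is not None and len(val):
        extra = set(val.labels) - set(train.class_set)
        if extra:
            raise ValueError(f"validation classes absent from train class_set: {sorted(extra)}")

    x = model._check_input(train.images)
    y = train.label_indices
    onehot_full = np.eye(model.config.n_classes, dtype=np.float32)[y]
    rng = np.random.default_rng(tc.seed)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}

    for epoch in range(tc.epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            probs, cache = model._forward(x[idx], cache=True)
            onehot = onehot_full[idx]
            eps = 1e-12
            losses.append(float(-(onehot * np.log(probs + eps)).sum() / len(idx)))
            grads = model._backward(probs, onehot, cache)
            for k, g in grads.items():
                velocity[k] = tc.momentum * velocity[k] + g
                model.params[k] -= tc.learning_rate * velocity[k]
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val is not None and len(val):
            vp = model.predict_probabilities(val)
            entry["val_accuracy"] = float((vp.argmax(axis=1) == val.label_indices).mean())
        model.history.append(entry)
    return model


def predict_probabilities(model: LightOCT, table: DatasetTable) -> np.ndarray:
    return model.predict_probabilities(table)


def randomize_labels(table: DatasetTable, granularity: str = "per-image",
                     seed: int = 0) -> DatasetTable:
    """Replace class labels with uniform draws from ``class_set``.

    ``per-image`` draws one label per record; ``per-subject`` draws one
    label per subject and applies it to all of the subject's records.
    Original labels are kept in the ``original_label`` shadow column so the
    test set can still be scored against the truth.
    """
    if len(table) == 0:
        raise ValueError("cannot randomize labels of an empty table")
    if granularity not in ("per-image", "per-subject"):
        raise ValueError(f"unknown granularity {granularity!r}")
    rng = np.random.default_rng(seed)
    classes = np.asarray(table.class_set, dtype=object)
    if granularity == "per-image":
        new = rng.choice(classes, size=len(table))
    else:
        subjects = table.meta["subject_id"]
        uniq = sorted(subjects.unique())
        lookup = dict(zip(uniq, rng.choice(classes, size=len(uniq))))
        new = subjects.map(lookup).to_numpy()
    return table.with_labels(new)


def history_to_csv(model: LightOCT, path) -> None:
    """Write the per-epoch training history (loss, val accuracy) as CSV."""
    import pandas as pd

    pd.DataFrame(model.history).to_csv(path, index=False)


def save_model(model: LightOCT, path) -> None:
    """Portable single-file parameter dump (npz)."""
    cfg = model.config
    np.savez(
        path,
        **model.params,
        _config=np.array([cfg.conv1_filters, cfg.conv2_filters, cfg.kernel_size,
                          cfg.input_height, cfg.input_width, cfg.n_classes]),
    )


def load_model(path) -> LightOCT:
    data = np.load(path)
    c = data["_config"]
    model = LightOCT(ModelConfig(*[int(v) for v in c]))
    for k in model.params:
        model.params[k] = data[k]
    return model
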