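"""Compact CNN for superpixel-patch classification, implemented in NumPy.

The network takes a fixed-size RGB patch (56x56 default, 75x75 optional),
scaled from 0-255 to 0-1, and outputs a softmax over tissue categories. The
architecture is six 3x3 convolutions of widths (32, 32, 64, 64, 128, 128)
with size-preserving padding, a 0.2 dropout followed by a 2x2 max-pool after
every conv pair, a flatten, a 256-unit ReLU dense layer and a softmax output.
With a 56x56x3 input and 6 classes this totals 1,894,438 trainable
parameters (~1.9 M).

Training uses Adam (learning rate 1e-3), categorical cross-entropy, Glorot
uniform initialization, and a max-norm-3 constraint on the weights incident
to each hidden unit, keeping the weights from the epoch with the highest
validation accuracy.

Everything — im2col convolutions, pooling, backprop, Adam — is plain NumPy
so the classifier runs anywhere, on CPU, with bit-reproducible seeding.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .superpixels import PatchDataset

__all__ = [
    "ArchitectureConfig",
    "TrainingConfig",
    "Model",
    "build_model",
    "count_parameters",
    "train",
    "predict",
]


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyperparameters pinning the network topology.

    ``conv_widths`` must have even length; a dropout + 2x2 max-pool follows
    every pair of convolutions. Convolutions preserve spatial size (zero
    padding), pooling halves it with floor on odd sizes.
    """

    input_side: int = 56
    conv_widths: Tuple[int, ...] = (32, 32, 64, 64, 128, 128)
    kernel: int = 3
    dense_width: int = 256
    n_classes: int = 6
    dropout_rate: float = 0.2
    max_norm: float = 3.0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if len(self.conv_widths) % 2 != 0 or not self.conv_widths:
            raise ValueError("conv_widths must come in conv-pair multiples")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd for size-preserving padding")
        side = self.input_side
        for _ in range(len(self.conv_widths) // 2):
            side //= 2
        if side < 1:
            raise ValueError("input_side too small for the pooling stages")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings.

    The batch size defaults follow the input side pairing (256 for 56-px
    patches, 150 for 75-px); pass ``batch_size`` to override, e.g. for small
    corpora. ``epochs`` defaults to 50; short schedules are fine on easily
    separable data.
    """

    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: Optional[int] = None
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    def resolved_batch_size(self, input_side: int) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return 256 if input_side == 56 else 150


# ---------------------------------------------------------------------------
# layers


def _glorot_uniform(rng: np.random.Generator, shape: Tuple[int, ...], fan_in: int, fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Conv2D:
    """3x3 'same' convolution via im2col; weights (k*k*c_in, c_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, dtype) -> None:
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        self.W = _glorot_uniform(rng, (fan_in, c_out), fan_in, fan_out, dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.trainable = True
        self.constrained = True  # max-norm applies per output filter (axis 0)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = np.empty((n, h, w, self.k * self.k, c), dtype=x.dtype)
        idx = 0
        for di in range(self.k):
            for dj in range(self.k):
                cols[:, :, :, idx, :] = xp[:, di : di + h, dj : dj + w, :]
                idx += 1
        return cols.reshape(n, h, w, self.k * self.k * c)

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        self._shape = x.shape
        cols = self._im2col(x)
        self._cols2d = cols.reshape(-1, cols.shape[-1])
        out = self._cols2d @ self.W + self.b
        n, h, w, _ = x.shape
        return out.reshape(n, h, w, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dout2d = dout.reshape(-1, self.c_out)
        self.dW = self._cols2d.T @ dout2d
        self.db = dout2d.sum(axis=0)
        dcols = (dout2d @ self.W.T).reshape(n, h, w, self.k * self.k, c)
        p = self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=dout.dtype)
        idx = 0
        for di in range(self.k):
            for dj in range(self.k):
                dxp[:, di : di + h, dj : dj + w, :] += dcols[:, :, :, idx, :]
                idx += 1
        self._cols2d = None
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return [("W", self.W), ("b", self.b)]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype) -> None:
        self.W = _glorot_uniform(rng, (n_in, n_out), n_in, n_out, dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.trainable = True
        self.constrained = True  # max-norm per unit = per column

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        self._x = None
        return dout @ self.W.T

    def params(self):
        return [("W", self.W), ("b", self.b)]


class ReLU:
    trainable = False

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = dout * self._mask
        self._mask = None
        return out


class Dropout:
    """Inverted dropout; identity at inference."""

    trainable = False

    def __init__(self, rate: float) -> None:
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


class MaxPool2x2:
    """2x2 max pooling, stride 2, floor on odd spatial sizes."""

    trainable = False

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2, :]
        self._in_shape = x.shape
        blocks = xc.reshape(n, h2, 2, w2, 2, c)
        out = blocks.max(axis=(2, 4))
        self._mask = blocks == out[:, :, None, :, None, :]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        # distribute among ties equally (exact for distinct values; ties are
        # measure-zero with float activations)
        counts = self._mask.sum(axis=(2, 4), keepdims=True)
        grad = self._mask * (dout[:, :, None, :, None, :] / counts)
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, : 2 * h2, : 2 * w2, :] = grad.reshape(n, 2 * h2, 2 * w2, c)
        self._mask = None
        return dx


class Flatten:
    trainable = False

    def forward(self, x: np.ndarray, training: bool, rng=None) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


# ---------------------------------------------------------------------------
# model


class Model:
    """The patch classifier: layer stack + softmax cross-entropy head."""

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0, dtype=np.float32) -> None:
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        layers: List = []
        c_in = 3
        side = cfg.input_side
        for i in range(0, len(cfg.conv_widths), 2):
            for w_out in cfg.conv_widths[i : i + 2]:
                layers.append(Conv2D(c_in, w_out, cfg.kernel, rng, dtype))
                layers.append(ReLU())
                c_in = w_out
            layers.append(Dropout(cfg.dropout_rate))
            layers.append(MaxPool2x2())
            side //= 2
        layers.append(Flatten())
        self.flatten_width = side * side * c_in
        layers.append(Dense(self.flatten_width, cfg.dense_width, rng, dtype))
        layers.append(ReLU())
        layers.append(Dense(cfg.dense_width, cfg.n_classes, rng, dtype))
        self.layers = layers

    # -- plumbing ----------------------------------------------------------

    def trainable_layers(self):
        return [l for l in self.layers if getattr(l, "trainable", False)]

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """Logits for a batch of scaled inputs (N, side, side, 3) in [0, 1]."""
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, patches: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Softmax probabilities for uint8 patches (N, side, side, 3)."""
        patches = np.asarray(patches)
        if patches.shape[1] != self.cfg.input_side:
            raise ValueError(
                f"patch side {patches.shape[1]} does not match model input "
                f"{self.cfg.input_side}"
            )
        probs = np.empty((patches.shape[0], self.cfg.n_classes), dtype=np.float64)
        for start in range(0, patches.shape[0], batch_size):
            x = patches[start : start + batch_size].astype(self.dtype) / 255.0
            probs[start : start + x.shape[0]] = _softmax(self.forward(x, training=False))
        return probs

    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for layer in self.trainable_layers() for _, p in layer.params()]

    def set_weights(self, weights: List[np.ndarray]) -> None:
        i = 0
        for layer in self.trainable_layers():
            for name, p in layer.params():
                p[...] = weights[i]
                i += 1

    def max_norm_excess(self) -> float:
        """Largest amount by which any constrained unit exceeds the norm cap."""
        worst = 0.0
        for layer in self.trainable_layers():
            if getattr(layer, "constrained", False):
                norms = np.sqrt((layer.W.astype(np.float64) ** 2).sum(axis=0))
                worst = max(worst, float(norms.max() - self.cfg.max_norm))
        return worst

    def save(self, path: str) -> None:
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(path, config=json.dumps(asdict(self.cfg)), **arrays)

    @classmethod
    def load(cls, path: str) -> "Model":
        data = np.load(path if path.endswith(".npz") else path + ".npz", allow_pickle=False)
        cfg_d = json.loads(str(data["config"]))
        cfg_d["conv_widths"] = tuple(cfg_d["conv_widths"])
        model = cls(ArchitectureConfig(**cfg_d))
        n = len(model.get_weights())
        model.set_weights([data[f"w{i}"] for i in range(n)])
        return model


def build_model(cfg: ArchitectureConfig = ArchitectureConfig(), seed: int = 0, dtype=np.float32) -> Model:
    """Instantiate the CNN with Glorot-uniform weights from ``seed``."""
    return Model(cfg, seed=seed, dtype=dtype)


def count_parameters(model_or_layer) -> int:
    """Exact count of trainable weights and biases."""
    if hasattr(model_or_layer, "trainable_layers"):
        layers = model_or_layer.trainable_layers()
    else:
        layers = [model_or_layer]
    return int(sum(p.size for layer in layers for _, p in layer.params()))


# ---------------------------------------------------------------------------
# loss / optimizer


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


class Adam:
    def __init__(self, model: Model, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for layer in model.trainable_layers() for _, p in layer.params()]
        self.v = [np.zeros_like(p) for layer in model.trainable_layers() for _, p in layer.params()]

    def step(self) -> None:
        self.t += 1
        i = 0
        for layer in self.model.trainable_layers():
            grads = {"W": layer.dW, "b": layer.db}
            for name, p in layer.params():
                g = grads[name]
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1**self.t)
                vhat = self.v[i] / (1 - self.b2**self.t)
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
                i += 1
            if getattr(layer, "constrained", False):
                _apply_max_norm(layer.W, self.model.cfg.max_norm)


def _apply_max_norm(W: np.ndarray, cap: float) -> None:
    """Rescale columns (weights incident to each unit/filter) to norm <= cap."""
    norms = np.sqrt((W**2).sum(axis=0, keepdims=True))
    scale = np.minimum(1.0, cap / np.maximum(norms, 1e-12))
    W *= scale.astype(W.dtype)


# ---------------------------------------------------------------------------
# training / inference


def _stratified_split(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        members = rng.permutation(members)
        n_val = int(np.floor(fraction * len(members)))
        n_val = min(n_val, len(members) - 1)  # keep at least one for training
        val_idx.append(members[:n_val])
        train_idx.append(members[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train(model: Model, train_set: PatchDataset, cfg: TrainingConfig = TrainingConfig()):
    """Fit the CNN on labeled patches; keep the best-validation-accuracy weights.

    A stratified ``validation_fraction`` of the patches is held out (seeded);
    each epoch shuffles the rest and runs Adam minibatch steps with the
    max-norm constraint applied after every update. Returns ``(model,
    history)`` where history rows carry per-epoch train/validation loss and
    accuracy; the model ends with the weights of the epoch that maximized
    validation accuracy.
    """
    if train_set.labels is None:
        raise ValueError("train_set must be labeled")
    y_all = np.asarray(train_set.labels)
    if len(np.unique(y_all)) < 2:
        raise ValueError("need at least 2 classes present in the training set")
    if train_set.side != model.cfg.input_side:
        raise ValueError("patch side does not match model input side")

    rng = np.random.default_rng(cfg.seed)
    tr_idx, va_idx = _stratified_split(y_all, cfg.validation_fraction, rng)
    if len(va_idx) == 0:
        raise ValueError("validation split is empty; provide more patches")
    present = set(np.unique(y_all[tr_idx]))
    if present != set(np.unique(y_all)):
        raise ValueError("a class vanished from the training split")

    x = train_set.patches.astype(model.dtype) / 255.0
    batch = cfg.resolved_batch_size(model.cfg.input_side)
    opt = Adam(model, cfg.learning_rate)

    history: List[Dict] = []
    best_acc, best_weights = -1.0, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), batch):
            sel = order[start : start + batch]
            xb, yb = x[sel], y_all[sel]
            logits = model.forward(xb, training=True, rng=rng)
            probs = _softmax(logits)
            losses.append(_cross_entropy(probs, yb) * len(sel))
            hits += int((probs.argmax(axis=1) == yb).sum())
            seen += len(sel)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            model.backward(((probs - onehot) / len(yb)).astype(model.dtype))
            opt.step()
        val_loss, val_acc = _evaluate(model, x[va_idx], y_all[va_idx], batch)
        history.append(
            {
                "epoch": epoch + 1,
                "train_loss": sum(losses) / seen,
                "train_acc": hits / seen,
                "val_loss": val_loss,
                "val_acc": val_acc,
            }
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.get_weights()
    model.set_weights(best_weights)
    return model, history


def _evaluate(model: Model, x: np.ndarray, y: np.ndarray, batch: int):
    losses, hits = [], 0
    for start in range(0, len(x), batch):
        xb, yb = x[start : start + batch], y[start : start + batch]
        probs = _softmax(model.forward(xb, training=False))
        losses.append(_cross_entropy(probs, yb) * len(yb))
        hits += int((probs.argmax(axis=1) == yb).sum())
    return sum(losses) / len(x), hits / len(x)


def predict(model: Model, patches: PatchDataset):
    """Class index + probability vector per patch, in dataset order."""
    probs = model.predict_proba(patches.patches)
    return probs.argmax(axis=1), probs


def history_to_csv(history: List[Dict], path: str) -> None:
    pd.DataFrame(history).to_csv(path, index=False)
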