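"""A compact convolutional classifier for raw 20x10 pressure images,
implemented directly on NumPy.

Architecture: three blocks of (3x3 convolution, stride 1, padding 1) ->
batch normalization -> ReLU -> (2x2 max pooling, stride 2), with 64, 128
and 256 output channels and pooling paddings (0,1), (1,1) and none, so a
20x10 input traces 20x10 -> 10x6 -> 6x4 -> 3x2 spatially and flattens to
3*2*256 = 1536 features feeding one fully connected layer of class
scores.  Training uses softmax cross-entropy and Adam (learning rate
1e-4) for 30 epochs at batch size 40.

Max-pool padding uses -inf semantics, so padded positions never win the
max; on the non-negative activations after ReLU this coincides with
zero padding.  Inputs are scaled from ADC counts to [0, 1].  All
forward/backward passes are vectorized ``im2col`` matrix products; the
model is deliberately small enough to train on a CPU in seconds to
minutes at the dataset sizes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import ADC_MAX, EvalResult
from .evaluation import macro_metrics

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class CNNSpec:
    """Architecture and training hyperparameters."""

    input_shape: tuple[int, int] = (20, 10)
    channels: tuple[int, ...] = (64, 128, 256)
    pool_pads: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (0, 0))
    n_classes: int = 18
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 40
    input_scale: float = float(ADC_MAX)

    def shape_trace(self) -> list[tuple[int, int]]:
        """Spatial sizes after each block; raises if any stage collapses."""
        h, w = self.input_shape
        trace = [(h, w)]
        for pr, pc in self.pool_pads:
            h, w = (h + 2 * pr) // 2, (w + 2 * pc) // 2
            if h < 1 or w < 1:
                raise ValueError("input too small for the pooling chain")
            trace.append((h, w))
        return trace

    @property
    def flat_features(self) -> int:
        h, w = self.shape_trace()[-1]
        return h * w * self.channels[-1]


# ---------------------------------------------------------------------------
# layers


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.standard_normal((c_in * 9, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        patches = sliding_window_view(xp, (3, 3), axis=(2, 3))  # b,c,h,w,3,3
        patches = patches.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * 9)
        self._patches, self._in_shape = patches, (b, c, h, w)
        out = patches @ self.W + self.b
        return out.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(b * h * w, -1)
        self.dW = self._patches.T @ dflat
        self.db = dflat.sum(axis=0)
        dpatch = (dflat @ self.W.T).reshape(b, h, w, c, 3, 3)
        dxp = np.zeros((b, c, h + 2, w + 2), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i : i + h, j : j + w] += dpatch[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, 1 : 1 + h, 1 : 1 + w]

    def grads(self):
        return [self.dW, self.db]


class _BatchNorm:
    def __init__(self, channels: int):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.params = [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean *= _BN_MOMENTUM
            self.running_mean += (1 - _BN_MOMENTUM) * mean
            self.running_var *= _BN_MOMENTUM
            self.running_var += (1 - _BN_MOMENTUM) * var
        else:
            mean, var = self.running_mean, self.running_var
        m = mean[None, :, None, None]
        v = var[None, :, None, None]
        self._xhat = (x - m) / np.sqrt(v + _BN_EPS)
        self._std = np.sqrt(v + _BN_EPS)
        return self.gamma[None, :, None, None] * self._xhat + self.beta[
            None, :, None, None
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.dgamma = (dout * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) / self._std
        return dx

    def grads(self):
        return [self.dgamma, self.dbeta]


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def grads(self):
        return []


class _MaxPool2x2:
    """2x2/stride-2 max pooling with optional spatial padding.

    Padded positions hold -inf so they can never win the max.
    """

    params: list = []

    def __init__(self, pad: tuple[int, int]):
        self.pad = pad

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        pr, pc = self.pad
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (pr, pr), (pc, pc)),
            constant_values=-np.inf,
        )
        b, c, h, w = xp.shape
        ho, wo = h // 2, w // 2
        win = xp.reshape(b, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(b, c, ho, wo, 4)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        pr, pc = self.pad
        b, c, h, w = self._in_shape
        ho, wo = dout.shape[2], dout.shape[3]
        dflat = np.zeros((b, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dxp = (
            dflat.reshape(b, c, ho, wo, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, 2 * ho, 2 * wo)
        )
        return dxp[:, :, pr : pr + h, pc : pc + w]

    def grads(self):
        return []


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def grads(self):
        return [self.dW, self.db]


# ---------------------------------------------------------------------------
# model


class CNNModel:
    """Three-block convolutional network over single-channel grid images."""

    def __init__(self, spec: CNNSpec, seed: int = 0):
        if spec.input_shape[0] < 4 or spec.input_shape[1] < 4:
            raise ValueError(f"input shape {spec.input_shape} too small")
        self.spec = spec
        spec.shape_trace()  # validates the pooling chain
        rng = np.random.default_rng(seed)
        self.layers = []
        c_in = 1
        for c_out, pad in zip(spec.channels, spec.pool_pads):
            self.layers += [
                _Conv3x3(c_in, c_out, rng),
                _BatchNorm(c_out),
                _ReLU(),
                _MaxPool2x2(pad),
            ]
            c_in = c_out
        self.fc = _Linear(spec.flat_features, spec.n_classes, rng)

    def n_parameters(self) -> int:
        total = 0
        for layer in self.layers + [self.fc]:
            total += sum(int(np.prod(p.shape)) for _, p in layer.params)
        return total

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise ValueError(
                f"expected images of shape {self.spec.input_shape}, got {x.shape[1:]}"
            )
        return (x / self.spec.input_scale)[:, None, :, :]

    def feature_map(self, images: np.ndarray) -> np.ndarray:
        """Pre-flatten activations, shape (B, C_last, H_last, W_last)."""
        x = self._prepare(images)
        for layer in self.layers:
            x = layer.forward(x, train=False)
        return x

    def forward(self, images: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._prepare(images)
        for layer in self.layers:
            x = layer.forward(x, train=train)
        self._pre_flat_shape = x.shape
        return self.fc.forward(x.reshape(x.shape[0], -1), train=train)

    def backward(self, dscores: np.ndarray) -> None:
        dx = self.fc.backward(dscores).reshape(self._pre_flat_shape)
        for layer in reversed(self.layers):
            dx = layer.backward(dx)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return self.forward(images, train=False).argmax(axis=1)


def build_model(spec: CNNSpec | None = None, seed: int = 0) -> CNNModel:
    """Construct the network; validates the spatial shape trace."""
    return CNNModel(spec or CNNSpec(), seed=seed)


class _Adam:
    def __init__(self, layers, lr: float):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.t = 0
        self.m = [
            [np.zeros_like(p) for _, p in layer.params] for layer in self.layers
        ]
        self.v = [
            [np.zeros_like(p) for _, p in layer.params] for layer in self.layers
        ]

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for li, layer in enumerate(self.layers):
            for pi, ((_, p), g) in enumerate(zip(layer.params, layer.grads())):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _softmax_xent(scores: np.ndarray, y: np.ndarray):
    shifted = scores - scores.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz
    loss = float(-logp[np.arange(len(y)), y].mean())
    dscores = np.exp(logp)
    dscores[np.arange(len(y)), y] -= 1.0
    return loss, (dscores / len(y)).astype(np.float32)


def train(
    model: CNNModel,
    images: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    epochs: int | None = None,
    batch_size: int | None = None,
    learning_rate: float | None = None,
) -> list[dict]:
    """Train with Adam and softmax cross-entropy; returns the per-epoch
    history of mean minibatch loss and training accuracy.

    ``labels`` must be integer class indices; at least two classes must
    be present.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs at least 2 classes")
    spec = model.spec
    epochs = epochs or spec.epochs
    batch_size = batch_size or spec.batch_size
    lr = learning_rate or spec.learning_rate
    rng = np.random.default_rng(seed)
    opt = _Adam(model.layers + [model.fc], lr)
    n = len(labels)
    history = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            scores = model.forward(images[idx], train=True)
            loss, dscores = _softmax_xent(scores, labels[idx])
            model.backward(dscores)
            opt.step()
            losses.append(loss)
            correct += int((scores.argmax(axis=1) == labels[idx]).sum())
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / n}
        )
    return history


# ---------------------------------------------------------------------------
# cross-validated evaluation on raw frames


def evaluate_cnn(
    images: np.ndarray,
    labels,
    subject_ids=None,
    scheme: str = "kfold",
    k: int = 10,
    seed: int = 0,
    spec: CNNSpec | None = None,
) -> EvalResult:
    """Cross-validate the CNN on raw images with the same fold schemes and
    macro metrics as the classical harness; the model is re-initialized
    and re-trained from scratch for every fold."""
    from sklearn.model_selection import LeaveOneGroupOut, StratifiedKFold

    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    y = np.searchsorted(np.asarray(classes, dtype=labels.dtype), labels)
    spec = spec or CNNSpec(n_classes=len(classes))
    if spec.n_classes != len(classes):
        raise ValueError(f"spec expects {spec.n_classes} classes, data has {len(classes)}")

    if scheme == "kfold":
        if k < 2:
            raise ValueError("k must be >= 2")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(images, y)
    elif scheme == "loso":
        groups = np.asarray(subject_ids)
        if len(np.unique(groups)) < 2:
            raise ValueError("LOSO needs at least 2 subjects")
        splits = LeaveOneGroupOut().split(images, y, groups)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    m = len(classes)
    pooled = np.zeros((m, m), dtype=int)
    per_fold = []
    for fold, (train_idx, test_idx) in enumerate(splits):
        model = build_model(spec, seed=seed + fold)
        train(model, images[train_idx], y[train_idx], seed=seed + fold)
        pred = model.predict(images[test_idx])
        cm = np.zeros((m, m), dtype=int)
        np.add.at(cm, (y[test_idx], pred), 1)
        pooled += cm
        acc, mp, mr, mf1 = macro_metrics(cm)
        per_fold.append({"accuracy": acc, "macro_p": mp, "macro_r": mr, "macro_f1": mf1})
    mean = {kk: float(np.mean([f[kk] for f in per_fold])) for kk in per_fold[0]}
    denom = mean["macro_p"] + mean["macro_r"]
    return EvalResult(
        scheme=scheme,
        classifier="cnn",
        accuracy=mean["accuracy"],
        macro_p=mean["macro_p"],
        macro_r=mean["macro_r"],
        macro_f1=2 * mean["macro_p"] * mean["macro_r"] / denom if denom > 0 else 0.0,
        per_fold=per_fold,
        confusion=pooled,
        labels=[str(c) for c in classes],
    )
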