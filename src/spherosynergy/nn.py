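"""A small dense-connectivity convolutional regression network in numpy.

The viability decoder is a DenseNet-style regressor: a strided stem
convolution, dense blocks whose 3x3 convolutions each see the concatenation
of every earlier feature map in the block (the characteristic shortcut
pattern of densely connected CNNs), 1x1 compression transitions with
average pooling, global average pooling, and a small fully connected head
ending in a single linear output.  It is deliberately compact — the decoding
task is a smooth monotone map from spheroid appearance to viability, and a
few thousand parameters train on a CPU in minutes.

Everything is plain numpy: im2col convolutions backed by BLAS matmuls,
explicit backward passes, Adam, mean-squared-error loss.  All randomness
(initialization, batch shuffling) flows through explicit seeds, so two runs
with the same seed produce bit-identical loss histories and weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Conv2d",
    "ReLU",
    "AvgPool2d",
    "GlobalAvgPool",
    "Linear",
    "DenseBlock",
    "Sequential",
    "DenseNetRegressor",
    "TrainHistory",
    "train_regressor",
]


class Param:
    """One learnable tensor with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class Layer:
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """2-D convolution via im2col; 'same'-style padding of kernel//2."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.w = Param(rng.normal(0.0, scale, size=(out_ch, fan_in)))
        self.b = Param(np.zeros(out_ch))
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride
        self.pad = kernel // 2

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, c, _, _ = xp.shape
        k, s = self.kernel, self.stride
        cols = np.empty((n, c, k, k, ho, wo), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, i, j] = xp[:, :, i : i + ho * s : s, j : j + wo * s : s]
        return cols.reshape(n, c * k * k, ho * wo)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {c}")
        k, s, p = self.kernel, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._cols = self._im2col(xp, ho, wo)
        self._xshape = x.shape
        out = np.matmul(self.w.value, self._cols) + self.b.value[:, None]
        return out.reshape(n, self.out_ch, ho, wo)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, f, ho, wo = grad.shape
        g = grad.reshape(n, f, ho * wo)
        self.w.grad += np.matmul(g, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.b.grad += g.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T, g)  # (n, c*k*k, ho*wo)
        k, s, p = self.kernel, self.stride, self.pad
        _, c, h, w = self._xshape
        dpatch = dcols.reshape(n, c, k, k, ho, wo)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + ho * s : s, j : j + wo * s : s] += dpatch[:, :, i, j]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]

    def params(self) -> list[Param]:
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        out = grad * self._mask
        self._mask = None
        return out


class AvgPool2d(Layer):
    """Non-overlapping average pooling by an integer factor."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        f = self.factor
        if h % f or w % f:
            raise ValueError(f"spatial size {h}x{w} not divisible by pool {f}")
        self._inshape = x.shape
        return x.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        f = self.factor
        g = grad[:, :, :, None, :, None] / (f * f)
        return np.broadcast_to(
            g, (n, c, h // f, f, w // f, f)
        ).reshape(n, c, h, w).copy()


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._inshape
        return np.broadcast_to(
            grad[:, :, None, None] / (h * w), (n, c, h, w)
        ).copy()


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_dim)
        self.w = Param(rng.normal(0.0, scale, size=(out_dim, in_dim)))
        self.b = Param(np.zeros(out_dim))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        out = grad @ self.w.value
        self._x = None
        return out

    def params(self) -> list[Param]:
        return [self.w, self.b]


class DenseBlock(Layer):
    """Dense connectivity: each 3x3 conv sees all earlier maps in the block."""

    def __init__(self, in_ch: int, n_layers: int, growth: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.convs = [
            Conv2d(in_ch + l * growth, growth, kernel=3, rng=rng)
            for l in range(n_layers)
        ]
        self.relus = [ReLU() for _ in range(n_layers)]
        self.in_ch = in_ch
        self.growth = growth
        self.out_ch = in_ch + n_layers * growth

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = [x]
        for conv, relu in zip(self.convs, self.relus):
            inp = np.concatenate(feats, axis=1)
            feats.append(relu.forward(conv.forward(inp)))
        self._sizes = [f.shape[1] for f in feats]
        return np.concatenate(feats, axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        splits = np.cumsum(self._sizes)[:-1]
        grads = [g.copy() for g in np.split(grad, splits, axis=1)]
        for l in reversed(range(len(self.convs))):
            dy = self.relus[l].backward(grads[l + 1])
            dinp = self.convs[l].backward(dy)
            inner = np.cumsum(self._sizes[: l + 1])[:-1]
            for k, piece in enumerate(np.split(dinp, inner, axis=1)):
                grads[k] += piece
        return grads[0]

    def params(self) -> list[Param]:
        return [p for conv in self.convs for p in conv.params()]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class Flatten1(Layer):
    """(n, 1) -> (n,) at the output head."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x[:, 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad[:, None]


class DenseNetRegressor:
    """Dense-connectivity CNN mapping (n, 1, s, s) images to n scalars.

    Architecture: 5x5 stride-2 stem conv -> ReLU -> 2x average pool, then
    ``len(block_layers)`` dense blocks separated by 1x1 compression
    transitions with 2x pooling, global average pooling, one hidden FC
    layer, linear scalar output (no output activation — the normalization
    stage owns the scale).
    """

    def __init__(
        self,
        input_size: int = 128,
        stem_channels: int = 8,
        block_layers: tuple[int, ...] = (2, 2),
        growth: int = 8,
        compression: float = 0.5,
        hidden: int = 16,
        seed: int = 0,
    ):
        self.config = dict(
            input_size=input_size,
            stem_channels=stem_channels,
            block_layers=tuple(block_layers),
            growth=growth,
            compression=compression,
            hidden=hidden,
            seed=seed,
        )
        rng = np.random.default_rng(seed)
        layers: list[Layer] = [
            Conv2d(1, stem_channels, kernel=5, stride=2, rng=rng),
            ReLU(),
            AvgPool2d(2),
        ]
        ch = stem_channels
        for bi, n_layers in enumerate(block_layers):
            block = DenseBlock(ch, n_layers, growth, rng=rng)
            layers.append(block)
            ch = block.out_ch
            if bi < len(block_layers) - 1:
                out_ch = max(int(round(ch * compression)), 4)
                layers += [Conv2d(ch, out_ch, kernel=1, rng=rng), ReLU(), AvgPool2d(2)]
                ch = out_ch
        layers += [
            GlobalAvgPool(),
            Linear(ch, hidden, rng=rng),
            ReLU(),
            Linear(hidden, 1, rng=rng),
            Flatten1(),
        ]
        self.net = Sequential(layers)
        # Input/target standardization, fitted at training time.
        self.x_mean = 0.0
        self.x_std = 1.0
        self.y_scale = 100.0

    # -- inference ---------------------------------------------------------
    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Predict scalars for (n, s, s) or (n, 1, s, s) images."""
        x = self._prepare(images)
        if len(x) == 0:
            return np.empty(0)
        out = [
            self.net.forward(x[i : i + batch_size])
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out) * self.y_scale

    def _prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (n, s, s) or (n, 1, s, s), got {x.shape}")
        if x.shape[2] != self.config["input_size"]:
            raise ValueError(
                f"expected {self.config['input_size']}px input, got {x.shape[2]}px"
            )
        return (x - self.x_mean) / self.x_std

    # -- persistence -------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.net.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.net.params(), weights, strict=True):
            p.value[...] = w

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.net.params())}
        cfg = dict(self.config)
        cfg["block_layers"] = list(cfg["block_layers"])
        np.savez(
            path,
            _config=json.dumps(cfg),
            _norm=np.array([self.x_mean, self.x_std, self.y_scale]),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "DenseNetRegressor":
        with np.load(path, allow_pickle=False) as data:
            cfg = json.loads(str(data["_config"]))
            cfg["block_layers"] = tuple(cfg["block_layers"])
            model = cls(**cfg)
            model.x_mean, model.x_std, model.y_scale = data["_norm"]
            model.set_weights([data[f"p{i}"] for i in range(len(model.net.params()))])
        return model


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    train_mse: list[float] = field(default_factory=list)
    val_mse: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_mse: float = np.inf


def _adam_step(params: list[Param], lr: float, t: int,
               beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
    for p in params:
        p.m = beta1 * p.m + (1 - beta1) * p.grad
        p.v = beta2 * p.v + (1 - beta2) * p.grad**2
        mhat = p.m / (1 - beta1**t)
        vhat = p.v / (1 - beta2**t)
        p.value -= lr * mhat / (np.sqrt(vhat) + eps)
        p.grad[...] = 0.0


def train_regressor(
    model: DenseNetRegressor,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    epochs: int = 60,
    batch_size: int = 32,
    lr: float = 3e-3,
    patience: int = 15,
    seed: int = 0,
) -> TrainHistory:
    """Minimize MSE on % viability; keep the best-validation-loss weights.

    Inputs are (n, s, s) images in [0, 1] and targets in % (0–100-ish).
    Targets are internally scaled by ``model.y_scale``; inputs standardized
    by the training-set mean/sd (stored on the model for inference).  When
    no validation set is given the training loss drives checkpointing.
    Deterministic given ``seed`` and fixed BLAS threading.
    """
    if len(x_train) == 0:
        raise ValueError("empty training set")
    x_train = np.asarray(x_train, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    model.x_mean = float(x_train.mean())
    model.x_std = float(x_train.std()) or 1.0

    have_val = x_val is not None and len(x_val) > 0
    rng = np.random.default_rng(seed)
    params = model.net.params()
    history = TrainHistory()
    best_weights = model.get_weights()
    t = 0
    since_best = 0
    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for start in range(0, len(order), batch_size):
            idx = order[start : start + batch_size]
            xb = model._prepare(x_train[idx])
            yb = y_train[idx] / model.y_scale
            pred = model.net.forward(xb)
            err = pred - yb
            epoch_losses.append(float(np.mean(err**2)))
            model.net.backward(2.0 * err / len(err))
            t += 1
            _adam_step(params, lr, t)
        train_mse = float(np.mean(epoch_losses)) * model.y_scale**2
        if have_val:
            val_pred = model.predict(x_val)
            val_mse = float(np.mean((val_pred - np.asarray(y_val)) ** 2))
        else:
            val_mse = train_mse
        history.epoch.append(epoch)
        history.train_mse.append(train_mse)
        history.val_mse.append(val_mse)
        if val_mse < history.best_val_mse:
            history.best_val_mse = val_mse
            history.best_epoch = epoch
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    model.set_weights(best_weights)
    return history
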