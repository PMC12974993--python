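"""Minimal deterministic CNN engine (numpy, hand-written backprop).

Implements exactly the pieces the exon-pair classifier needs: 3x3
same-padded convolutions, ReLU, 2x2 max-pooling, dense layers, inverted
dropout, a sigmoid output with class-weighted binary cross-entropy, and
Adam. Everything is float32 and driven by a single ``numpy.random
.Generator``, so training is bit-reproducible for a fixed seed and the
serialized weights reload exactly.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*k*k) patch matrix for same-size convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # cols: (N, C, H, W, k, k) -> (N, H, W, C, k, k)
    return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * w, c * k * k
    )


def _col2im(dcols: np.ndarray, shape: tuple, k: int = 3, pad: int = 1) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, h, w = shape
    d6 = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di : di + h, dj : dj + w] += d6[:, :, :, :, di, dj]
    return dxp[:, :, pad : pad + h, pad : pad + w]


class Conv2D:
    """3x3 same-padded convolution; weights He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = (rng.standard_normal((c_out, c_in * k * k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.k // 2)
        out = cols @ self.w.T + self.b
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        d2 = dout.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        self.dw = (d2.T @ cols).astype(np.float32)
        self.db = d2.sum(axis=0).astype(np.float32)
        return _col2im((d2 @ self.w).astype(np.float32), xshape, self.k, self.k // 2)

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; ties route the gradient to the first max."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        return (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    def params(self):
        return []


class Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)

    def params(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = (self._x.T @ dout).astype(np.float32)
        self.db = dout.sum(axis=0).astype(np.float32)
        return dout @ self.w.T

    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class Dropout:
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_from_logits(
    z: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, np.ndarray]:
    """Class-weighted binary cross-entropy on logits; returns (loss, dL/dz)."""
    p = sigmoid(z)
    eps = 1e-12
    loss = -np.mean(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    dz = w * (p - y) / len(z)
    return float(loss), dz.astype(np.float32)


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name, param, gradname in layer.params():
                g = getattr(layer, gradname)
                m, v = self.state.get(
                    (li, name),
                    (np.zeros_like(param), np.zeros_like(param)),
                )
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                self.state[(li, name)] = (m, v)
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                param -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                    np.float32
                )


class SmallCNN:
    """conv16-pool-conv32-pool-dense64-dropout-dense1 binary classifier."""

    def __init__(
        self,
        input_hw: tuple[int, int],
        conv_channels: tuple[int, int],
        dense_units: int,
        dropout: float,
        rng: np.random.Generator,
    ):
        h, w = input_hw
        if h % 4 or w % 4:
            raise ValueError("input height/width must be divisible by 4")
        c1, c2 = conv_channels
        self.layers = [
            Conv2D(1, c1, 3, rng),
            ReLU(),
            MaxPool2(),
            Conv2D(c1, c2, 3, rng),
            ReLU(),
            MaxPool2(),
            Flatten(),
            Dense(c2 * (h // 4) * (w // 4), dense_units, rng),
            ReLU(),
            Dropout(dropout, rng),
            Dense(dense_units, 1, rng),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train)
        return out[:, 0]

    def backward(self, dz: np.ndarray) -> None:
        dout = dz[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict_proba(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        outs = [
            sigmoid(self.forward(x[s : s + batch], train=False))
            for s in range(0, len(x), batch)
        ]
        return np.concatenate(outs) if outs else np.empty(0)

    # -- weight (de)serialization -------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.layers):
            for name, param, _ in layer.params():
                out[f"layer{li}_{name}"] = param.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.layers):
            for name, param, _ in layer.params():
                key = f"layer{li}_{name}"
                if weights[key].shape != param.shape:
                    raise ValueError(f"weight shape mismatch for {key}")
                param[...] = weights[key]
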