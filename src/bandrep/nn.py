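"""Minimal NumPy implementation of the small 2-D CNN used by the classifier.

Self-contained layers with forward/backward passes, an Adam optimizer and a
softmax cross-entropy loss. Data layout is NHWC: (batch, height, width,
channels); the classifier feeds windows as (batch, n_channels, 60, 1).

Conventions match the framework defaults the architecture tables imply:

* convolutions use 'same' padding (for an even kernel the extra pad goes on
  the bottom/right) so spatial size is preserved;
* 2x2 max pooling with stride 2 uses floor semantics (a trailing odd row or
  column is dropped), so 5 -> 2 and 25 -> 12;
* dropout is inverted dropout, active only while training.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2DSame",
    "MaxPool2x2",
    "ReLU",
    "Dropout",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]

_DTYPE = np.float32


class Layer:
    name = "layer"
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, shape: tuple) -> tuple:
        """Output shape for an input of shape (h, w, c), batch omitted."""
        return shape

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


def _same_pads(k: int) -> tuple[int, int]:
    total = k - 1
    return total // 2, total - total // 2


class Conv2DSame(Layer):
    """2-D convolution, stride 1, 'same' zero padding, He-initialized."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator | None = None, name: str = "conv2d"):
        super().__init__()
        self.name = name
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        rng = rng or np.random.default_rng()
        fan_in = kernel * kernel * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(kernel, kernel, in_channels, out_channels))
        self.W = w.astype(_DTYPE)
        self.b = np.zeros(out_channels, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def output_shape(self, shape):
        h, w, _ = shape
        return (h, w, self.out_channels)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        pt, pb = _same_pads(k)
        xp = np.pad(x, ((0, 0), (pt, pb), (pt, pb), (0, 0)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # cols: (B, H, W, C, k, k) -> (B*H*W, k*k*C)
        b, h, w = cols.shape[:3]
        cols = cols.transpose(0, 1, 2, 4, 5, 3).reshape(b * h * w, k * k * x.shape[3])
        return cols

    def forward(self, x, training):
        x = x.astype(_DTYPE, copy=False)
        self._x_shape = x.shape
        b, h, w, _ = x.shape
        cols = self._im2col(x)
        self._cols = cols
        wmat = self.W.transpose(0, 1, 2, 3).reshape(-1, self.out_channels)
        out = cols @ wmat + self.b
        return out.reshape(b, h, w, self.out_channels)

    def backward(self, dout):
        b, h, w, co = dout.shape
        dflat = dout.reshape(-1, co).astype(_DTYPE, copy=False)
        wmat = self.W.reshape(-1, co)
        self.grads[0][...] = (self._cols.T @ dflat).reshape(self.W.shape)
        self.grads[1][...] = dflat.sum(axis=0)
        dcols = dflat @ wmat.T  # (B*H*W, k*k*Cin)
        k, ci = self.kernel, self.in_channels
        pt, pb = _same_pads(k)
        hp, wp = h + pt + pb, w + pt + pb
        dxp = np.zeros((b, hp, wp, ci), dtype=_DTYPE)
        dcols = dcols.reshape(b, h, w, k, k, ci)
        # scatter-add each kernel offset back onto the padded input
        for di in range(k):
            for dj in range(k):
                dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, pt:pt + h, pb:pb + w, :]


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2, floor semantics (odd remainder dropped)."""

    def __init__(self, name: str = "max_pooling2d"):
        super().__init__()
        self.name = name

    def output_shape(self, shape):
        h, w, c = shape
        return (h // 2, w // 2, c)

    def forward(self, x, training):
        b, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :h2 * 2, :w2 * 2, :]
        self._in_shape = x.shape
        blocks = xc.reshape(b, h2, 2, w2, 2, c)
        flat = blocks.transpose(0, 1, 3, 5, 2, 4).reshape(b, h2, w2, c, 4)
        self._argmax = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, dout):
        b, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((b, h2, w2, c, 4), dtype=_DTYPE)
        np.put_along_axis(dflat, self._argmax[..., None],
                          dout[..., None].astype(_DTYPE, copy=False), axis=-1)
        dx = np.zeros((b, h, w, c), dtype=_DTYPE)
        blocks = dflat.reshape(b, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx[:, :h2 * 2, :w2 * 2, :] = blocks.reshape(b, h2 * 2, w2 * 2, c)
        return dx


class ReLU(Layer):
    def __init__(self, name: str = "relu"):
        super().__init__()
        self.name = name

    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None,
                 name: str = "dropout"):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self.name = name

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def __init__(self, name: str = "flatten"):
        super().__init__()
        self.name = name

    def output_shape(self, shape):
        return (int(np.prod(shape)),)

    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        super().__init__()
        self.name = name
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features),
                            size=(in_features, out_features)).astype(_DTYPE)
        self.b = np.zeros(out_features, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def output_shape(self, shape):
        return (self.out_features,)

    def forward(self, x, training):
        self._x = x.astype(_DTYPE, copy=False)
        return self._x @ self.W + self.b

    def backward(self, dout):
        dout = dout.astype(_DTYPE, copy=False)
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Sequential:
    """Ordered layer stack with a softmax head applied outside the layers."""

    def __init__(self, layers: list[Layer], input_shape: tuple):
        self.layers = layers
        self.input_shape = tuple(input_shape)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [softmax(self.forward(x[i:i + batch_size], training=False))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs)

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def summary(self) -> list[tuple[str, tuple, int]]:
        """(layer name, output shape with leading None, trainable params)."""
        rows = []
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.output_shape(shape)
            rows.append((layer.name, (None, *shape), layer.n_params))
        return rows

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                out[f"{i}_{layer.name}_{j}"] = p
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = weights[f"{i}_{layer.name}_{j}"]


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray,
                          onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(logits)
    loss = -float(np.sum(onehot * np.log(np.clip(p, 1e-12, None))) / n)
    return loss, (p - onehot) / n
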