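"""Minimal NumPy neural-network core for the gait TCNs.

Implements exactly the layer vocabulary the temporal and spatial networks
need — dilated 1-D convolution (length-preserving or causal), batch
normalization, ReLU, inverted dropout, a position-wise linear map, temporal
average pooling and a residual block — together with hand-written backward
passes, BCE-with-logits / MSE losses and an Adam optimizer.  Shapes follow
the (batch, channels, length) convention throughout.

The backward passes are verified against central finite differences in the
test suite; keep any change here gradient-checked.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32  # training dtype; float64 available per layer for checks

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "ChannelLinear",
    "GlobalAvgPool1d",
    "Linear",
    "Sequential",
    "ResidualBlock1d",
    "Adam",
    "bce_with_logits",
    "mse_loss",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base class: parameters and gradients live in dicts keyed by name."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Dilated 1-D convolution, stride 1.

    padding="same" pads symmetrically so the output length equals the input
    length (kernel must be odd).  padding="causal" pads on the left only and
    chomps nothing (the left pad plays the role of pad-then-chomp), so
    output[t] depends only on input[:t+1].
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        dilation: int = 1,
        padding: str = "same",
        rng: np.random.Generator | None = None,
        dtype=None,
    ) -> None:
        super().__init__()
        self.dtype = dtype or DTYPE
        if padding not in ("same", "causal"):
            raise ValueError(f"unknown padding mode {padding!r}")
        if padding == "same" and kernel_size % 2 == 0:
            raise ValueError("'same' padding requires an odd kernel")
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size
        # He initialization (ReLU nonlinearities downstream)
        w = rng.standard_normal((out_channels, in_channels, kernel_size))
        self.params["w"] = (w * np.sqrt(2.0 / fan_in)).astype(self.dtype)
        self.params["b"] = np.zeros(out_channels, dtype=self.dtype)
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.padding = padding
        self.in_channels = in_channels
        self.out_channels = out_channels
        self._cache: tuple | None = None

    def _pads(self) -> tuple[int, int]:
        total = self.dilation * (self.kernel_size - 1)
        if self.padding == "same":
            return total // 2, total - total // 2
        return total, 0

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        n, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        left, right = self._pads()
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        k, d = self.kernel_size, self.dilation
        cols = np.stack([xp[:, :, i * d : i * d + length] for i in range(k)], axis=2)
        # one big GEMM: (c_in*k, n*L) gathered columns
        cols2 = cols.reshape(n, c * k, length).transpose(1, 0, 2).reshape(c * k, n * length)
        w2 = self.params["w"].reshape(self.out_channels, c * k)
        out = (w2 @ cols2).reshape(self.out_channels, n, length).transpose(1, 0, 2)
        out += self.params["b"][:, None]
        self._cache = (cols2, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols2, xshape = self._cache
        n, c, length = xshape
        k, d = self.kernel_size, self.dilation
        w2 = self.params["w"].reshape(self.out_channels, c * k)
        dout2 = dout.transpose(1, 0, 2).reshape(self.out_channels, n * length)
        self.grads["w"] = (dout2 @ cols2.T).reshape(self.params["w"].shape)
        self.grads["b"] = dout.sum(axis=(0, 2))
        dcols = (w2.T @ dout2).reshape(c, k, n, length).transpose(2, 0, 1, 3)
        lpad, rpad = self._pads()
        dxp = np.zeros((n, c, length + lpad + rpad), dtype=self.dtype)
        for i in range(k):
            dxp[:, :, i * d : i * d + length] += dcols[:, :, i, :]
        return dxp[:, :, lpad : lpad + length]


class BatchNorm1d(Layer):
    """Per-channel batch normalization over batch and time axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=None) -> None:
        super().__init__()
        self.dtype = dtype or DTYPE
        self.params["gamma"] = np.ones(channels, dtype=self.dtype)
        self.params["beta"] = np.zeros(channels, dtype=self.dtype)
        self.running_mean = np.zeros(channels, dtype=self.dtype)
        self.running_var = np.ones(channels, dtype=self.dtype)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2), dtype=self.dtype)
            var = x.var(axis=(0, 2), dtype=self.dtype)
            self.running_mean += (self.momentum * (mean - self.running_mean)).astype(self.dtype)
            self.running_var += (self.momentum * (var - self.running_var)).astype(self.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = (1.0 / np.sqrt(var + self.eps)).astype(self.dtype)
        xhat = (x - mean[:, None]) * inv[:, None]
        self._cache = (xhat, inv, training, x.shape)
        return self.params["gamma"][:, None] * xhat + self.params["beta"][:, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, training, shape = self._cache
        gamma = self.params["gamma"]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] = dout.sum(axis=(0, 2))
        dxhat = dout * gamma[:, None]
        if not training:
            return dxhat * inv[:, None]
        m = shape[0] * shape[2]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True)
        )
        del m
        return term * inv[:, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity when rate == 0 or in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        mask = self.rng.random(x.shape) < keep
        self._mask = mask.astype(x.dtype) / x.dtype.type(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class ChannelLinear(Layer):
    """Position-wise fully connected map applied at every time step.

    Equivalent to a kernel-1 convolution; used as the FCN head that turns
    TCN features into per-sample event logits.
    """

    def __init__(self, in_channels: int, out_channels: int, rng=None, dtype=None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.dtype = dtype or DTYPE
        self.params["w"] = (
            rng.standard_normal((out_channels, in_channels)) * np.sqrt(1.0 / in_channels)
        ).astype(self.dtype)
        self.params["b"] = np.zeros(out_channels, dtype=self.dtype)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.dtype)
        n, c, length = x.shape
        self._x2 = x.transpose(1, 0, 2).reshape(c, n * length)
        out = self.params["w"] @ self._x2
        out = out.reshape(-1, n, length).transpose(1, 0, 2)
        return out + self.params["b"][:, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, o, length = dout.shape
        dout2 = dout.transpose(1, 0, 2).reshape(o, n * length)
        self.grads["w"] = dout2 @ self._x2.T
        self.grads["b"] = dout.sum(axis=(0, 2))
        dx = self.params["w"].T @ dout2
        return dx.reshape(-1, n, length).transpose(1, 0, 2)


class GlobalAvgPool1d(Layer):
    """Mean over the time axis: (n, c, L) -> (n, c)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._length, axis=2) / self._length


class Linear(Layer):
    """Dense map on (n, features)."""

    def __init__(self, in_features: int, out_features: int, rng=None, dtype=None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.dtype = dtype or DTYPE
        self.params["w"] = (
            rng.standard_normal((out_features, in_features)) * np.sqrt(1.0 / in_features)
        ).astype(self.dtype)
        self.params["b"] = np.zeros(out_features, dtype=self.dtype)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["w"]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        out = []
        for layer in self.layers:
            if isinstance(layer, (Sequential, ResidualBlock1d)):
                out.extend(layer.parameters())
            elif layer.params:
                out.append(layer)
        return out


class ResidualBlock1d(Layer):
    """sTCN residual block: two causal dilated convolutions, each followed by
    ReLU and dropout, with an additive bypass (1x1 conv when channel counts
    differ)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        dilation: int,
        dropout: float,
        rng: np.random.Generator | None = None,
        dtype=None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        dtype = dtype or DTYPE
        self.body = Sequential(
            Conv1d(in_channels, out_channels, kernel_size, dilation, "causal", rng, dtype),
            ReLU(),
            Dropout(dropout, rng),
            Conv1d(out_channels, out_channels, kernel_size, dilation, "causal", rng, dtype),
            ReLU(),
            Dropout(dropout, rng),
        )
        self.shortcut = (
            None
            if in_channels == out_channels
            else Conv1d(in_channels, out_channels, 1, 1, "causal", rng, dtype)
        )

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        out = self.body.forward(x, training)
        res = x if self.shortcut is None else self.shortcut.forward(x, training)
        return out + res

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = self.body.backward(dout)
        if self.shortcut is None:
            return dx + dout
        return dx + self.shortcut.backward(dout)

    def parameters(self):
        out = self.body.parameters()
        if self.shortcut is not None:
            out.append(self.shortcut)
        return out


class Adam:
    """Adam with the standard bias correction (beta1 0.9, beta2 0.999)."""

    def __init__(self, layers, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params.items()} for layer in layers
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for key, param in layer.params.items():
                g = layer.grads[key]
                m[key] = b1 * m[key] + (1 - b1) * g
                v[key] = b2 * v[key] + (1 - b2) * g * g
                mhat = m[key] / corr1
                vhat = v[key] / corr2
                param -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(param.dtype)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy on raw logits; returns (loss, dlogits)."""
    n = logits.size
    # log(1 + exp(-|z|)) formulation for stability
    loss = np.mean(np.maximum(logits, 0) - logits * targets + np.log1p(np.exp(-np.abs(logits))))
    dlogits = (sigmoid(logits) - targets) / n
    return loss, dlogits


def mse_loss(pred: np.ndarray, targets: np.ndarray):
    diff = pred - targets
    return float(np.mean(diff**2)), 2.0 * diff / diff.size
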