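"""Minimal numpy neural-network primitives for the hybrid CNN-LSTM regressor.

Implements exactly the layers the BMI model needs — 2-D convolution, ReLU,
batch normalization, max pooling, an LSTM, dense layers and inverted dropout
— with explicit forward/backward passes and Adam/RMSprop/SGD optimizers.
Tensors follow the (batch, channel, space, time) layout; the time axis is
preserved through the convolutional stack so the LSTM can consume it.

All randomness (initialization, shuffling, dropout masks) flows through
numpy Generators supplied by the caller, so training is reproducible from a
single integer seed.
"""

from __future__ import annotations

import numpy as np


def _sliding(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # (N, C, H, W) -> (N, C, H-kh+1, W-kw+1, kh, kw)
    return np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))


class Layer:
    """Base layer: parameter/gradient registry plus forward/backward."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []
        self.decay: list[bool] = []  # True where L2 weight decay applies

    def add_param(self, value: np.ndarray, decay: bool = False) -> np.ndarray:
        self.params.append(value)
        self.grads.append(np.zeros_like(value))
        self.decay.append(decay)
        return value

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params)


class Conv2D(Layer):
    """Valid-mode 2-D convolution (cross-correlation), stride 1.

    Uses an im2col layout so forward and both backward products are plain
    BLAS matmuls. ``skip_input_grad`` elides the input-gradient scatter for
    layers sitting directly on the data.
    """

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kh: int,
        kw: int,
        rng,
        skip_input_grad: bool = False,
    ):
        super().__init__()
        fan_in = in_ch * kh * kw
        scale = np.sqrt(2.0 / fan_in)  # He init for the ReLU that follows
        self.W = self.add_param(
            rng.normal(0, scale, (out_ch, in_ch, kh, kw)).astype(np.float32),
            decay=True,
        )
        self.b = self.add_param(np.zeros(out_ch, dtype=np.float32))
        self.kh, self.kw = kh, kw
        self.skip_input_grad = skip_input_grad

    def forward(self, x, train):
        if x.shape[2] < self.kh or x.shape[3] < self.kw:
            raise ValueError(
                f"conv input spatial shape {x.shape[2:]} smaller than "
                f"kernel ({self.kh}, {self.kw})"
            )
        N, C, H, W = x.shape
        Ho, Wo = H - self.kh + 1, W - self.kw + 1
        # (N, C, Ho, Wo, kh, kw) -> (N*Ho*Wo, C*kh*kw) contiguous
        cols = (
            _sliding(x, self.kh, self.kw)
            .transpose(0, 2, 3, 1, 4, 5)
            .reshape(N * Ho * Wo, C * self.kh * self.kw)
        )
        self._cols = cols
        self._in_shape = x.shape
        Wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ Wmat.T + self.b
        return out.reshape(N, Ho, Wo, -1).transpose(0, 3, 1, 2)

    def backward(self, g):
        N, C, H, W = self._in_shape
        O = self.W.shape[0]
        Ho, Wo = H - self.kh + 1, W - self.kw + 1
        gmat = g.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, O)
        self.grads[0][...] = (gmat.T @ self._cols).reshape(self.W.shape)
        self.grads[1][...] = gmat.sum(axis=0)
        if self.skip_input_grad:
            return None
        dcols = (gmat @ self.W.reshape(O, -1)).reshape(
            N, Ho, Wo, C, self.kh, self.kw
        )
        dx = np.zeros(self._in_shape, dtype=g.dtype)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, :, i : i + Ho, j : j + Wo] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, g):
        return np.where(self._mask, g, 0.0)


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (batch, space, time)."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        super().__init__()
        self.gamma = self.add_param(np.ones(channels, dtype=np.float32))
        self.beta = self.add_param(np.zeros(channels, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            )
        else:
            mean, var = self.running_mean, self.running_var
        shp = (1, -1, 1, 1)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shp)) * self._inv_std.reshape(shp)
        self._train = train
        return self.gamma.reshape(shp) * self._xhat + self.beta.reshape(shp)

    def backward(self, g):
        shp = (1, -1, 1, 1)
        axes = (0, 2, 3)
        self.grads[0][...] = (g * self._xhat).sum(axis=axes)
        self.grads[1][...] = g.sum(axis=axes)
        gx = g * self.gamma.reshape(shp)
        if not self._train:
            return gx * self._inv_std.reshape(shp)
        m = g.shape[0] * g.shape[2] * g.shape[3]
        return (
            self._inv_std.reshape(shp)
            / m
            * (
                m * gx
                - gx.sum(axis=axes).reshape(shp)
                - self._xhat * (gx * self._xhat).sum(axis=axes).reshape(shp)
            )
        )


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing remainder rows/cols are dropped."""

    def __init__(self, ph: int, pw: int):
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x, train):
        N, C, H, W = x.shape
        Ho, Wo = H // self.ph, W // self.pw
        if Ho < 1 or Wo < 1:
            raise ValueError(
                f"pool ({self.ph}, {self.pw}) collapses input of shape {x.shape}"
            )
        xt = x[:, :, : Ho * self.ph, : Wo * self.pw]
        self._in_shape = x.shape
        xr = (
            xt.reshape(N, C, Ho, self.ph, Wo, self.pw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, Ho, Wo, self.ph * self.pw)
        )
        self._idx = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        N, C, H, W = self._in_shape
        Ho, Wo = H // self.ph, W // self.pw
        dxr = np.zeros((N, C, Ho, Wo, self.ph * self.pw), dtype=g.dtype)
        np.put_along_axis(dxr, self._idx[..., None], g[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=g.dtype)
        dx[:, :, : Ho * self.ph, : Wo * self.pw] = (
            dxr.reshape(N, C, Ho, Wo, self.ph, self.pw)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, Ho * self.ph, Wo * self.pw)
        )
        return dx


class TimeFlatten(Layer):
    """(N, C, H, W) -> (N, W, C*H): keep time, flatten channel and space."""

    def forward(self, x, train):
        self._shape = x.shape
        N, C, H, W = x.shape
        return x.transpose(0, 3, 1, 2).reshape(N, W, C * H)

    def backward(self, g):
        N, C, H, W = self._shape
        return g.reshape(N, W, C, H).transpose(0, 2, 3, 1)


class LSTM(Layer):
    """Single LSTM layer over (N, T, D); gates ordered (i, f, o, g)."""

    def __init__(self, input_size: int, hidden: int, rng, return_sequences: bool):
        super().__init__()
        scale = 1.0 / np.sqrt(input_size + hidden)
        self.W = self.add_param(
            rng.normal(0, scale, (input_size + hidden, 4 * hidden)).astype(
                np.float32
            ),
            decay=True,
        )
        b = np.zeros(4 * hidden, dtype=np.float32)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = self.add_param(b)
        self.hidden = hidden
        self.return_sequences = return_sequences

    def forward(self, x, train):
        N, T, D = x.shape
        H = self.hidden
        self._x = x
        h = np.zeros((N, H), dtype=x.dtype)
        c = np.zeros((N, H), dtype=x.dtype)
        self._cache = []
        hs = np.empty((N, T, H), dtype=x.dtype)
        for t in range(T):
            z = np.concatenate([x[:, t, :], h], axis=1)
            a = z @ self.W + self.b
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H : 2 * H])
            o = _sigmoid(a[:, 2 * H : 3 * H])
            g = np.tanh(a[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((z, i, f, o, g, c, tanh_c))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._hs = hs
        return hs if self.return_sequences else hs[:, -1, :]

    def backward(self, grad):
        N, T, D = self._x.shape
        H = self.hidden
        if self.return_sequences:
            gh_seq = grad
        else:
            gh_seq = np.zeros((N, T, H), dtype=grad.dtype)
            gh_seq[:, -1, :] = grad
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dx = np.empty((N, T, D), dtype=grad.dtype)
        gh_next = np.zeros((N, H), dtype=grad.dtype)
        gc_next = np.zeros((N, H), dtype=grad.dtype)
        for t in range(T - 1, -1, -1):
            z, i, f, o, g, c_prev, tanh_c = self._cache[t]
            gh = gh_seq[:, t, :] + gh_next
            gc = gc_next + gh * o * (1 - tanh_c**2)
            go = gh * tanh_c
            gi = gc * g
            gg = gc * i
            gf = gc * c_prev
            da = np.concatenate(
                [
                    gi * i * (1 - i),
                    gf * f * (1 - f),
                    go * o * (1 - o),
                    gg * (1 - g**2),
                ],
                axis=1,
            )
            dW += z.T @ da
            db += da.sum(axis=0)
            dz = da @ self.W.T
            dx[:, t, :] = dz[:, :D]
            gh_next = dz[:, D:]
            gc_next = gc * f
        self.grads[0][...] = dW
        self.grads[1][...] = db
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng):
        super().__init__()
        scale = np.sqrt(2.0 / in_dim)
        self.W = self.add_param(
            rng.normal(0, scale, (in_dim, out_dim)).astype(np.float32), decay=True
        )
        self.b = self.add_param(np.zeros(out_dim, dtype=np.float32))

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference. ``rng`` set by the trainer."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / x.dtype.type(
            keep
        )
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        return g * self._mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Optimizer:
    def __init__(self, layers: list[Layer], lr: float, l2: float):
        self.layers = layers
        self.lr = lr
        self.l2 = l2

    def _iter(self):
        for layer in self.layers:
            for p, g, decay in zip(layer.params, layer.grads, layer.decay):
                if decay and self.l2 > 0:
                    g = g + self.l2 * p
                yield p, g

    def step(self):
        raise NotImplementedError


class SGD(Optimizer):
    def step(self):
        for p, g in self._iter():
            p -= self.lr * g


class RMSprop(Optimizer):
    def __init__(self, layers, lr, l2, rho=0.9, eps=1e-8):
        super().__init__(layers, lr, l2)
        self.rho, self.eps = rho, eps
        self.v = [
            [np.zeros_like(p) for p in layer.params] for layer in self.layers
        ]

    def step(self):
        k = 0
        state = [v for vs in self.v for v in vs]
        for p, g in self._iter():
            v = state[k]
            v[...] = self.rho * v + (1 - self.rho) * g**2
            p -= self.lr * g / (np.sqrt(v) + self.eps)
            k += 1


class Adam(Optimizer):
    def __init__(self, layers, lr, l2, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(layers, lr, l2)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for layer in layers for p in layer.params]
        self.v = [np.zeros_like(p) for layer in layers for p in layer.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        k = 0
        for p, g in self._iter():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g**2
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            k += 1


OPTIMIZERS = {"sgd": SGD, "rmsprop": RMSprop, "adam": Adam}
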