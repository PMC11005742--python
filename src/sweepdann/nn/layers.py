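"""Layer primitives with explicit forward/backward passes.

Tensors follow the NCHW convention for convolutional layers. Every layer
exposes ``params`` / ``grads`` dicts (empty when parameter-free) so the
optimizer can walk a network generically.
"""

from __future__ import annotations

import numpy as np


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def train(self, mode: bool = True):
        self.training = mode


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {
            "W": rng.normal(0.0, scale, size=(n_in, n_out)),
            "b": np.zeros(n_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"][...] = self._x.T @ grad
        self.grads["b"][...] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout with a private RNG stream (reproducible ablations)."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class BatchNorm(Layer):
    """Batch normalisation over the batch (and spatial axes for 4-D input)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params = {"gamma": np.ones(n_features), "beta": np.zeros(n_features)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3)

    def _shape(self, x, v):
        return v if x.ndim == 2 else v.reshape(1, -1, 1, 1)

    def forward(self, x):
        axes = self._axes(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - self._shape(x, mean)) / self._shape(x, self._std)
        return self._shape(x, self.params["gamma"]) * self._xhat + self._shape(
            x, self.params["beta"]
        )

    def backward(self, grad):
        axes = self._axes(grad)
        m = np.prod([grad.shape[a] for a in axes])
        self.grads["gamma"][...] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"][...] = grad.sum(axis=axes)
        g = grad * self._shape(grad, self.params["gamma"])
        if self.training:
            # full batch-norm backward (mean/var depend on the batch)
            dxhat = g
            dx = (
                dxhat
                - self._shape(grad, dxhat.mean(axis=axes))
                - self._xhat * self._shape(grad, (dxhat * self._xhat).mean(axis=axes))
            ) / self._shape(grad, self._std)
            return dx
        return g / self._shape(grad, self._std)


def _im2col(x, kh, kw):
    """x (B,C,H,W), valid windows -> (B, Ho, Wo, C*kh*kw)."""
    B, C, H, W = x.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    s0, s1, s2, s3 = x.strides
    shape = (B, C, Ho, Wo, kh, kw)
    strides = (s0, s1, s2, s3, s2, s3)
    cols = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    return cols.transpose(0, 2, 3, 1, 4, 5).reshape(B, Ho, Wo, C * kh * kw)


class Conv2D(Layer):
    """Same-padded 2-D convolution."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, int], rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        fan_in = c_in * kh * kw
        self.params = {
            "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in * kh * kw, c_out)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.ph, self.pw = (kh - 1) // 2, (kw - 1) // 2
        # 'same' padding requires odd kernels for exact symmetry
        self._pad = ((0, 0), (0, 0), (self.ph, kh - 1 - self.ph), (self.pw, kw - 1 - self.pw))

    def forward(self, x):
        B, C, H, W = x.shape
        if C != self.c_in:
            raise ValueError(f"Conv2D expected {self.c_in} channels, got {C}")
        xp = np.pad(x, self._pad)
        self._xp_shape = xp.shape
        cols = _im2col(xp, self.kh, self.kw)  # (B, H, W, C*kh*kw)
        self._cols = cols
        out = cols @ self.params["W"] + self.params["b"]  # (B, H, W, c_out)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad):
        B, Co, H, W = grad.shape
        g = grad.transpose(0, 2, 3, 1)  # (B,H,W,Co)
        flat_g = g.reshape(-1, Co)
        flat_cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.grads["W"][...] = flat_cols.T @ flat_g
        self.grads["b"][...] = flat_g.sum(axis=0)
        dcols = flat_g @ self.params["W"].T  # (B*H*W, C*kh*kw)
        dcols = dcols.reshape(B, H, W, self.c_in, self.kh, self.kw)
        dxp = np.zeros(self._xp_shape)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        ph0, ph1 = self._pad[2]
        pw0, pw1 = self._pad[3]
        return dxp[
            :,
            :,
            ph0 : dxp.shape[2] - ph1 if ph1 else dxp.shape[2],
            pw0 : dxp.shape[3] - pw1 if pw1 else dxp.shape[3],
        ]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; input spatial dims must divide the pool."""

    def __init__(self, pool: tuple[int, int], name: str = "pool"):
        super().__init__()
        self.ph, self.pw = pool
        self.name = name

    def forward(self, x):
        B, C, H, W = x.shape
        if H % self.ph or W % self.pw:
            raise ValueError(
                f"{self.name}: input {H}x{W} not divisible by pool {self.ph}x{self.pw}"
            )
        Ho, Wo = H // self.ph, W // self.pw
        xr = x.reshape(B, C, Ho, self.ph, Wo, self.pw)
        self._xr_shape = xr.shape
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, Ho, Wo, -1)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad):
        B, C, Ho, Wo = grad.shape
        flat = np.zeros((B, C, Ho, Wo, self.ph * self.pw))
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        xr = flat.reshape(B, C, Ho, Wo, self.ph, self.pw).transpose(0, 1, 2, 4, 3, 5)
        return xr.reshape(self._in_shape)


class GradReverse(Layer):
    """Identity forward; backward multiplies the gradient by -lambda."""

    def __init__(self, lam: float = 1.0):
        super().__init__()
        self.lam = lam

    def forward(self, x):
        return x

    def backward(self, grad):
        return -self.lam * grad


class Residual(Layer):
    """y = ReLU(x + f(x)) with f a Sequential whose output shape matches x."""

    def __init__(self, inner):
        super().__init__()
        self.inner = inner

    @property
    def layers(self):
        return self.inner.layers

    def train(self, mode: bool = True):
        self.training = mode
        self.inner.train(mode)

    def forward(self, x):
        y = x + self.inner.forward(x)
        self._mask = y > 0
        return y * self._mask

    def backward(self, grad):
        g = grad * self._mask
        return g + self.inner.backward(g)


class SimpleRNN(Layer):
    """Tanh recurrent layer consuming (B, T, D), returning the last hidden state."""

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.n_hidden = n_hidden
        s_in = np.sqrt(1.0 / n_in)
        s_h = np.sqrt(1.0 / n_hidden)
        self.params = {
            "Wx": rng.normal(0, s_in, size=(n_in, n_hidden)),
            "Wh": rng.normal(0, s_h, size=(n_hidden, n_hidden)),
            "b": np.zeros(n_hidden),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x):
        B, T, D = x.shape
        self._x = x
        self._h = np.zeros((T + 1, B, self.n_hidden))
        for t in range(T):
            self._h[t + 1] = np.tanh(
                x[:, t] @ self.params["Wx"] + self._h[t] @ self.params["Wh"] + self.params["b"]
            )
        return self._h[-1]

    def backward(self, grad):
        B, T, D = self._x.shape
        for k in self.grads:
            self.grads[k][...] = 0.0
        dx = np.zeros_like(self._x)
        dh = grad
        for t in range(T - 1, -1, -1):
            dz = dh * (1.0 - self._h[t + 1] ** 2)
            self.grads["Wx"] += self._x[:, t].T @ dz
            self.grads["Wh"] += self._h[t].T @ dz
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t] = dz @ self.params["Wx"].T
            dh = dz @ self.params["Wh"].T
        return dx
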