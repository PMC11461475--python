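"""Minimal trainable modules with explicit gradients.

The pipeline is trained by backpropagation through time with the boxcar
surrogate standing in for the spike threshold's derivative.  Every module
implements ``forward`` and ``backward`` with hand-derived gradients and
exposes its trainable buffers through ``param_items()`` as
``(name, value_array, grad_array)`` triples; the value arrays are updated in
place by the optimizer so that masks and Dale signs (applied functionally on
top of the raw buffers) are never disturbed.

All computations run in float64: the sizes involved are desk-scale and this
keeps the training path directly comparable to the float64 reference
implementations used as oracles.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .network import SpikingLayer, apply_dale
from .neuron import boxcar_surrogate, clamp_parameters

__all__ = [
    "Dense",
    "LeakyReLU",
    "LayerNorm",
    "ChannelDropout",
    "Conv2dMel",
    "AvgPoolTime",
    "log_softmax",
    "log_softmax_backward",
    "LIFNerve",
    "SNNLayer",
    "Adam",
    "global_norm_clip",
]

ParamItem = Tuple[str, np.ndarray, np.ndarray]


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: Optional[float] = None):
        scale = scale if scale is not None else 1.0 / np.sqrt(n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self.W.shape[0])
        dy2 = dy.reshape(-1, self.W.shape[1])
        self.dW += x2.T @ dy2
        self.db += dy2.sum(axis=0)
        return dy @ self.W.T

    def param_items(self) -> List[ParamItem]:
        return [("W", self.W, self.dW), ("b", self.b, self.db)]


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)

    def param_items(self) -> List[ParamItem]:
        return []


class LayerNorm:
    """Normalization over the last axis with learnable gain and bias."""

    def __init__(self, n_features: int, eps: float = 1e-5):
        self.g = np.ones(n_features)
        self.b = np.zeros(n_features)
        self.dg = np.zeros_like(self.g)
        self.db = np.zeros_like(self.b)
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return self.g * xhat + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        lead = tuple(range(dy.ndim - 1))
        self.dg += (dy * xhat).sum(axis=lead)
        self.db += dy.sum(axis=lead)
        dxhat = dy * self.g
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)

    def param_items(self) -> List[ParamItem]:
        return [("g", self.g, self.dg), ("b", self.b, self.db)]


class ChannelDropout:
    """Dropout on the channel dimension of (B, T, F, C) activations."""

    def __init__(self, p: float):
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, train: bool, rng: Optional[np.random.Generator]) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = (rng.random((x.shape[0], 1, 1, x.shape[3])) >= self.p)
        self._mask = keep / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask

    def param_items(self) -> List[ParamItem]:
        return []


class Conv2dMel:
    """2-d convolution over (time, mel) with a (7, 7) kernel, stride 1.

    The time axis is padded symmetrically so the frame count is unchanged;
    the feature axis is not padded, so 80 Mel bins yield 80 - 7 + 1 = 74
    feature positions per channel.  Output shape is (B, T, 74, C): each
    signal tracks the spectral energy of seven adjacent Mel bins.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 kernel: Tuple[int, int] = (7, 7)):
        kt, kf = kernel
        self.kt, self.kf = kt, kf
        self.K = rng.normal(0.0, 1.0 / np.sqrt(kt * kf), (channels, kt, kf))
        self.bias = np.zeros(channels)
        self.dK = np.zeros_like(self.K)
        self.dbias = np.zeros_like(self.bias)
        self._xp = None

    def out_features(self, n_mels: int) -> int:
        return n_mels - self.kf + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, n_mels = x.shape
        nf = self.out_features(n_mels)
        pt = self.kt // 2
        xp = np.pad(x, ((0, 0), (pt, pt), (0, 0)))
        self._xp = xp
        out = np.zeros((B, T, nf, self.K.shape[0]))
        for i in range(self.kt):
            for j in range(self.kf):
                out += xp[:, i:i + T, j:j + nf, None] * self.K[None, None, None, :, i, j]
        return out + self.bias

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, nf, C = dout.shape
        pt = self.kt // 2
        xp = self._xp
        dxp = np.zeros_like(xp)
        for i in range(self.kt):
            for j in range(self.kf):
                self.dK[:, i, j] += np.einsum("btf,btfc->c", xp[:, i:i + T, j:j + nf], dout)
                dxp[:, i:i + T, j:j + nf] += dout @ self.K[:, i, j]
        self.dbias += dout.sum(axis=(0, 1, 2))
        return dxp[:, pt:pt + T]

    def param_items(self) -> List[ParamItem]:
        return [("K", self.K, self.dK), ("bias", self.bias, self.dbias)]


class AvgPoolTime:
    """Non-overlapping average pooling over the time axis by factor k."""

    def __init__(self, k: int):
        self.k = int(k)
        self._in_T = None

    def out_steps(self, T: int) -> int:
        return T // self.k

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, F = x.shape
        Tp = T // self.k
        if Tp < 1:
            raise ValueError(f"sequence of {T} steps shorter than pooling kernel {self.k}")
        self._in_T = T
        return x[:, : Tp * self.k].reshape(B, Tp, self.k, F).mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, Tp, F = dy.shape
        dx = np.zeros((B, self._in_T, F))
        dx[:, : Tp * self.k] = np.repeat(dy / self.k, self.k, axis=1)
        return dx

    def param_items(self) -> List[ParamItem]:
        return []


def log_softmax(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=-1, keepdims=True)
    z = x - m
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def log_softmax_backward(y: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Gradient through log-softmax given its output y and upstream dy."""
    return dy - np.exp(y) * dy.sum(axis=-1, keepdims=True)


class LIFNerve:
    """Auditory nerve fibers: LIF neurons, no recurrence, trainable tau_u.

    Converts the real-valued auditory CNN signals into spike trains.  Each
    fiber has a single trainable parameter, its membrane time constant.
    """

    def __init__(self, n_fibers: int, dt: float, rng: np.random.Generator):
        self.n_fibers = n_fibers
        self.dt = float(dt)
        self.tau_u = rng.uniform(3.0, 25.0, n_fibers)
        self.dtau_u = np.zeros_like(self.tau_u)
        self._cache = None

    def forward(self, I: np.ndarray) -> np.ndarray:
        B, T, F = I.shape
        alpha = np.exp(-self.dt / self.tau_u)
        u = np.zeros((B, T, F))
        s = np.zeros((B, T, F))
        up = np.zeros((B, F))
        sp = np.zeros((B, F))
        for t in range(T):
            ut = alpha * (up - sp) + (1.0 - alpha) * I[:, t]
            st = (ut >= 1.0).astype(float)
            u[:, t] = ut
            s[:, t] = st
            up, sp = ut, st
        self._cache = (I, u, s, alpha)
        return s

    def backward(self, gs: np.ndarray) -> np.ndarray:
        I, u, s, alpha = self._cache
        B, T, F = I.shape
        dI = np.zeros((B, T, F))
        du_next = np.zeros((B, F))
        dalpha = np.zeros(F)
        for t in range(T - 1, -1, -1):
            ds = gs[:, t] - alpha * du_next
            du = ds * boxcar_surrogate(u[:, t]) + alpha * du_next
            dI[:, t] = (1.0 - alpha) * du
            up = u[:, t - 1] if t > 0 else np.zeros((B, F))
            sp = s[:, t - 1] if t > 0 else np.zeros((B, F))
            dalpha += (du * (up - sp - I[:, t])).sum(axis=0)
            du_next = du
        self.dtau_u += dalpha * alpha * self.dt / self.tau_u ** 2
        return dI

    def clamp(self) -> None:
        np.clip(self.tau_u, 3.0, 25.0, out=self.tau_u)

    def param_items(self) -> List[ParamItem]:
        return [("tau_u", self.tau_u, self.dtau_u)]


class SNNLayer:
    """Trainable AdLIF layer; wraps a :class:`SpikingLayer` for structure.

    The raw weight buffers and neuron parameters live on the wrapped
    ``SpikingLayer``, so masks, Dale signs and the zero recurrent diagonal
    are enforced identically during training and analysis.
    """

    def __init__(self, core: SpikingLayer):
        self.core = core
        n, n_in = core.spec.n_neurons, core.n_inputs
        self.dW_raw = np.zeros((n, n_in))
        self.dV_raw = np.zeros((n, n))
        self.dtau_u = np.zeros(n)
        self.dtau_w = np.zeros(n)
        self.da = np.zeros(n)
        self.db = np.zeros(n)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, n_inputs) spikes (or real signals); returns spikes."""
        core = self.core
        p = core.params
        sfa = np.asarray(p.sfa_enabled, dtype=float)
        a, b = p.a * sfa, p.b * sfa
        alpha = np.exp(-core.dt / p.tau_u)
        beta = np.exp(-core.dt / p.tau_w)
        W, V = core.W, core.V
        B, T, _ = x.shape
        n = core.spec.n_neurons
        ff = x @ W.T
        u = np.zeros((B, T, n))
        w = np.zeros((B, T, n))
        s = np.zeros((B, T, n))
        I = np.zeros((B, T, n))
        up = np.zeros((B, n))
        wp = np.zeros((B, n))
        sp = np.zeros((B, n))
        for t in range(T):
            It = ff[:, t] + sp @ V.T
            ut = alpha * (up - sp) + (1.0 - alpha) * (It - wp)
            wt = beta * (wp + b * sp) + (1.0 - beta) * a * up
            st = (ut >= 1.0).astype(float)
            I[:, t], u[:, t], w[:, t], s[:, t] = It, ut, wt, st
            up, wp, sp = ut, wt, st
        self._cache = (x, I, u, w, s, alpha, beta, a, b, W, V)
        return s

    def backward(self, gs: np.ndarray) -> np.ndarray:
        """gs: dL/ds for this layer's spikes; returns dL/dx for its input."""
        x, I, u, w, s, alpha, beta, a, b, W, V = self._cache
        B, T, n = u.shape
        dI = np.zeros((B, T, n))
        du_next = np.zeros((B, n))
        dw_next = np.zeros((B, n))
        dI_next = np.zeros((B, n))
        dalpha = np.zeros(n)
        dbeta = np.zeros(n)
        da = np.zeros(n)
        db = np.zeros(n)
        zeros = np.zeros((B, n))
        for t in range(T - 1, -1, -1):
            ds = gs[:, t] - alpha * du_next + beta * b * dw_next + dI_next @ V
            du = ds * boxcar_surrogate(u[:, t]) + alpha * du_next + (1.0 - beta) * a * dw_next
            dw = -(1.0 - alpha) * du_next + beta * dw_next
            dIt = (1.0 - alpha) * du
            dI[:, t] = dIt
            up = u[:, t - 1] if t > 0 else zeros
            wp = w[:, t - 1] if t > 0 else zeros
            sp = s[:, t - 1] if t > 0 else zeros
            dalpha += (du * (up - sp - I[:, t] + wp)).sum(axis=0)
            dbeta += (dw * (wp + b * sp - a * up)).sum(axis=0)
            da += (dw * (1.0 - beta) * up).sum(axis=0)
            db += (dw * beta * sp).sum(axis=0)
            du_next, dw_next, dI_next = du, dw, dIt

        core = self.core
        p = core.params
        dW_eff = np.einsum("btn,bti->ni", dI, x)
        dV_eff = np.einsum("btn,bti->ni", dI[:, 1:], s[:, :-1]) if T > 1 else 0.0
        # chain through mask and (optional) Dale magnitude map
        dW = dW_eff * core.ff_mask
        if core.input_signs is not None:
            dW = dW * core.input_signs[None, :] * np.sign(core.W_raw)
        dV = dV_eff * core.rec_mask
        if core.signs is not None:
            dV = dV * core.signs[None, :] * np.sign(core.V_raw)
        self.dW_raw += dW
        self.dV_raw += dV
        sfa = np.asarray(p.sfa_enabled, dtype=float)
        self.dtau_u += dalpha * alpha * core.dt / p.tau_u ** 2
        self.dtau_w += dbeta * beta * core.dt / p.tau_w ** 2 * sfa
        self.da += da * sfa
        self.db += db * sfa
        return dI @ W

    def clamp(self) -> None:
        p = clamp_parameters(self.core.params, self.core.dt)
        c = self.core.params
        c.tau_u[...] = p.tau_u
        c.tau_w[...] = p.tau_w
        c.a[...] = p.a
        c.b[...] = p.b

    def param_items(self) -> List[ParamItem]:
        c = self.core
        return [
            ("W_raw", c.W_raw, self.dW_raw),
            ("V_raw", c.V_raw, self.dV_raw),
            ("tau_u", c.params.tau_u, self.dtau_u),
            ("tau_w", c.params.tau_w, self.dtau_w),
            ("a", c.params.a, self.da),
            ("b", c.params.b, self.db),
        ]


def global_norm_clip(items: List[ParamItem], max_norm: float) -> float:
    total = np.sqrt(sum(float((g * g).sum()) for _, _, g in items))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for _, _, g in items:
            g *= scale
    return total


class Adam:
    """Adam optimizer over (name, value, grad) triples; updates in place."""

    def __init__(self, items: List[ParamItem], lr: float = 2e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.items = items
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in items]
        self.v = [np.zeros_like(v) for _, v, _ in items]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for (name, val, grad), m, v in zip(self.items, self.m, self.v):
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            val -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for _, _, g in self.items:
            g[...] = 0.0
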