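"""Minimal numpy neural-network core used by the regression models.

Implements exactly the pieces the blood-pressure networks need — 2-D
convolution with time-axis dilation, batch normalization, the adaptive
normalization layer (a learnable blend of an identity path and a
batch-normalized path), leaky rectifier, an LSTM with a linear head,
an adaptive-moment (Adam) optimizer with coupled L2 and global-norm
gradient clipping, and the piecewise learning-rate schedule.  Forward
passes cache what the hand-written backward passes need; gradients are
validated against finite differences in the test suite.

Array layout is channels-last: activations are (N, H, W, C) for the
convolutional stack and (N, T, D) for the recurrent stack.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "BatchNorm2D",
    "AdaptiveNorm",
    "LeakyReLU",
    "RowCollapse",
    "Sequential",
    "LSTM",
    "TimeLinear",
    "Adam",
    "global_norm_clip",
    "piecewise_lr",
]


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base class: parameter dict, matching grad dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for key, value in self.params.items():
            self.grads[key] = np.zeros_like(value)


class Conv2D(Layer):
    """Same-size 2-D convolution, dilated along the time (W) axis only.

    Kernel (kh, kw); the H axis (4 signal-channel rows) always uses
    dilation 1 while the W axis uses ``dilation``.  Symmetric zero
    padding keeps the spatial size; for even kernels the extra pad
    sample goes to the trailing side.
    """

    def __init__(self, in_c: int, out_c: int, kernel=(3, 3), dilation: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        kh, kw = kernel
        self.kh, self.kw = kh, kw
        self.dil = int(dilation)
        self.in_c, self.out_c = in_c, out_c
        fan_in = kh * kw * in_c
        self.params["W"] = _glorot_uniform(rng, (kh, kw, in_c, out_c), fan_in,
                                           kh * kw * out_c)
        self.params["b"] = np.zeros(out_c)
        # symmetric same-padding; (kh-1) rows, (kw-1)*dil time samples in total
        ph, pw = (kh - 1), (kw - 1) * self.dil
        self.pads = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        pt, pb, pl, pr = self.pads
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        self._xp = xp
        self._shape = x.shape
        n, h, w, _ = x.shape
        weight = self.params["W"]
        # per-tap accumulation beats an unfolded GEMM at these small sizes
        y = np.zeros((n, h, w, self.out_c))
        for i in range(self.kh):
            for j in range(self.kw):
                y += xp[:, i:i + h, j * self.dil:j * self.dil + w, :] @ weight[i, j]
        return y + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._shape
        pt, pb, pl, pr = self.pads
        weight = self.params["W"]
        dxp = np.zeros_like(self._xp)
        for i in range(self.kh):
            for j in range(self.kw):
                patch = self._xp[:, i:i + h, j * self.dil:j * self.dil + w, :]
                self.grads["W"][i, j] += np.tensordot(
                    patch, dy, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i:i + h, j * self.dil:j * self.dil + w, :] += dy @ weight[i, j].T
        self.grads["b"] += dy.sum(axis=(0, 1, 2))
        return dxp[:, pt:pt + h, pl:pl + w, :]


class BatchNorm2D(Layer):
    """Per-channel batch normalization over the (N, H, W) axes.

    Training mode normalizes with mini-batch statistics (population
    variance) and tracks running statistics with momentum; evaluation
    mode uses the running statistics, so with mini-batch size 1 the
    train-time behaviour coincides with instance normalization while
    inference stays deterministic.
    """

    def __init__(self, channels: int, affine: bool = True, eps: float = 1e-5,
                 momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.affine = affine
        if affine:
            self.params["gamma"] = np.ones(channels)
            self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 1, 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._xhat, self._inv_std = xhat, inv_std
        self._m = x.shape[0] * x.shape[1] * x.shape[2]
        self._training = training
        if self.affine:
            return self.params["gamma"] * xhat + self.params["beta"]
        return xhat

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._xhat, self._inv_std, self._m
        if self.affine:
            self.grads["gamma"] += (dy * xhat).sum(axis=(0, 1, 2))
            self.grads["beta"] += dy.sum(axis=(0, 1, 2))
            dxhat = dy * self.params["gamma"]
        else:
            dxhat = dy
        if not self._training:
            return dxhat * inv_std
        sum_dxhat = dxhat.sum(axis=(0, 1, 2))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (inv_std / m) * (m * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class AdaptiveNorm(Layer):
    """Learnable blend of identity and batch-normalized paths.

    ``y = lam * x + mu * BN(x)`` with scalar learnables initialized to
    (lam, mu) = (1, 0), i.e. the exact identity at initialization; the
    inner normalization carries no affine parameters of its own.
    """

    def __init__(self, channels: int, lambda_init: float = 1.0,
                 mu_init: float = 0.0) -> None:
        super().__init__()
        self.params["lam"] = np.array(float(lambda_init))
        self.params["mu"] = np.array(float(mu_init))
        self.bn = BatchNorm2D(channels, affine=False)
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        self._bnx = self.bn.forward(x, training)
        return self.params["lam"] * x + self.params["mu"] * self._bnx

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["lam"] += np.sum(dy * self._x)
        self.grads["mu"] += np.sum(dy * self._bnx)
        return self.params["lam"] * dy + self.bn.backward(self.params["mu"] * dy)

    def zero_grad(self) -> None:
        super().zero_grad()
        if hasattr(self, "bn"):
            self.bn.zero_grad()


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.slope * dy)


class RowCollapse(Layer):
    """Regression head: learnable linear collapse (H, C) -> scalar per column.

    Maps an (N, H, W, C) activation to an (N, W) output:
    ``y[n, w] = sum_{h,c} x[n, h, w, c] * A[h, c] + b`` — one shared
    linear read-out applied at every time column, turning the 4-row,
    C-channel feature image into the length-W waveform.
    """

    def __init__(self, rows: int, channels: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan = rows * channels
        self.params["A"] = _glorot_uniform(rng, (rows, channels), fan, 1)
        self.params["b"] = np.zeros(())
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return np.einsum("nhwc,hc->nw", x, self.params["A"]) + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["A"] += np.einsum("nhwc,nw->hc", self._x, dy)
        self.grads["b"] += dy.sum()
        return dy[:, None, :, None] * self.params["A"][None, :, None, :]


class Sequential:
    """Ordered container with grouped layers for block-level inspection.

    ``groups`` is a list of (name, [layers]) pairs; forward/backward
    runs through the flattened order.
    """

    def __init__(self, groups: list[tuple[str, list[Layer]]]) -> None:
        self.groups = groups
        self.layers = [layer for _, block in groups for layer in block]

    @property
    def n_layer_groups(self) -> int:
        return len(self.groups)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def parameters(self) -> list[tuple[str, Layer, str]]:
        """Flat list of (unique name, owning layer, param key)."""
        out = []
        for gi, (gname, block) in enumerate(self.groups):
            for li, layer in enumerate(block):
                items = [(layer, layer.params)]
                if isinstance(layer, AdaptiveNorm):
                    pass  # inner BN has no learnables
                for owner, params in items:
                    for key in params:
                        out.append((f"{gi}:{gname}:{li}:{key}", owner, key))
        return out

    def n_parameters(self) -> int:
        return sum(owner.params[key].size for _, owner, key in self.parameters())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTM(Layer):
    """Single-layer LSTM, gate rows stacked in the order (i, f, g, o).

    Input (N, T, D) -> hidden sequence (N, T, H).  The stacked input
    weight matrix has 4*H rows, matching the conventional printed
    shape (e.g. 1600 x D for 400 hidden units).
    """

    def __init__(self, in_dim: int, hidden: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_dim, self.hidden = in_dim, hidden
        self.params["Wx"] = _glorot_uniform(rng, (4 * hidden, in_dim), in_dim, hidden)
        self.params["Wh"] = _glorot_uniform(rng, (4 * hidden, hidden), hidden, hidden)
        self.params["b"] = np.zeros(4 * hidden)
        # forget-gate bias of 1 is the standard stable initialization
        self.params["b"][hidden:2 * hidden] = 1.0
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, t_len, _ = x.shape
        hdim = self.hidden
        h = np.zeros((n, hdim))
        c = np.zeros((n, hdim))
        self._cache = []
        self._x = x
        hs = np.empty((n, t_len, hdim))
        wx, wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        for t in range(t_len):
            z = x[:, t] @ wx.T + h @ wh.T + b
            i = _sigmoid(z[:, :hdim])
            f = _sigmoid(z[:, hdim:2 * hdim])
            g = np.tanh(z[:, 2 * hdim:3 * hdim])
            o = _sigmoid(z[:, 3 * hdim:])
            c_prev = c
            c = f * c_prev + i * g
            tanh_c = np.tanh(c)
            h_prev = h
            h = o * tanh_c
            self._cache.append((i, f, g, o, c_prev, tanh_c, h_prev))
            hs[:, t] = h
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        n, t_len, _ = self._x.shape
        hdim = self.hidden
        wx, wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros_like(self._x)
        dh_next = np.zeros((n, hdim))
        dc_next = np.zeros((n, hdim))
        for t in reversed(range(t_len)):
            i, f, g, o, c_prev, tanh_c, h_prev = self._cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c ** 2) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2),
                 do * o * (1 - o)], axis=1)
            self.grads["Wx"] += dz.T @ self._x[:, t]
            self.grads["Wh"] += dz.T @ h_prev
            self.grads["b"] += dz.sum(axis=0)
            dx[:, t] = dz @ wx
            dh_next = dz @ wh
            dc_next = dc * f
        return dx


class TimeLinear(Layer):
    """Linear head applied at every time step: (N, T, H) -> (N, T)."""

    def __init__(self, in_dim: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = _glorot_uniform(rng, (in_dim,), in_dim, 1)
        self.params["b"] = np.zeros(())
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += np.einsum("nth,nt->h", self._x, dy)
        self.grads["b"] += dy.sum()
        return dy[..., None] * self.params["W"]


def global_norm_clip(grads: list[np.ndarray], threshold: float) -> float:
    """Scale all gradients in place so their joint L2 norm <= threshold.

    Returns the pre-clip global norm.
    """
    total = float(np.sqrt(sum(float(np.sum(g ** 2)) for g in grads)))
    if total > threshold > 0:
        scale = threshold / total
        for g in grads:
            g *= scale
    return total


def piecewise_lr(initial: float, drop_factor: float, drop_period: int,
                 iteration: int) -> float:
    """Step-decay schedule: drop by ``drop_factor`` every ``drop_period``
    iterations (0-based iteration counter)."""
    return initial * drop_factor ** (iteration // drop_period)


class Adam:
    """Adaptive-moment optimizer with coupled L2 and global-norm clipping.

    The L2 penalty is added to the raw gradient (classical coupled
    form), then the joint gradient vector is clipped to ``grad_clip``
    in L2 norm, then the moment updates run with decay rates
    (beta1, beta2) and the given epsilon.
    """

    def __init__(self, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, l2: float = 0.0, grad_clip: float = 0.0) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.l2, self.grad_clip = l2, grad_clip
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, named_params: list[tuple[str, Layer, str]], lr: float) -> None:
        self.t += 1
        grads = []
        for name, owner, key in named_params:
            g = owner.grads[key]
            if self.l2:
                g = g + self.l2 * owner.params[key]
            grads.append(np.asarray(g, dtype=np.float64))
        if self.grad_clip:
            global_norm_clip(grads, self.grad_clip)
        for (name, owner, key), g in zip(named_params, grads):
            if name not in self.m:
                self.m[name] = np.zeros_like(owner.params[key])
                self.v[name] = np.zeros_like(owner.params[key])
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g ** 2
            mhat = self.m[name] / (1 - self.beta1 ** self.t)
            vhat = self.v[name] / (1 - self.beta2 ** self.t)
            owner.params[key] -= lr * mhat / (np.sqrt(vhat) + self.eps)
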