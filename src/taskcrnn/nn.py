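"""NumPy neural-network layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``grads`` during ``backward``.  All
arithmetic is float32; batches carry an explicit leading batch axis.

The convolution layer is *time-distributed*: input ``[B, T, X, Y, Z, C]``
is folded to ``[B*T, X, Y, Z, C]`` so the identical 3D kernels act
independently at every time step, preserving the time axis for the
recurrent stage.
"""

from __future__ import annotations

import itertools

import numpy as np

from taskcrnn.errors import ShapeError

DTYPE = np.float32


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    """Base layer: ``params`` / ``grads`` dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grads(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


def conv_output_size(n: int, k: int, s: int) -> int:
    """Valid-padding output extent: floor((n - k) / s) + 1."""
    return (n - k) // s + 1


class TimeDistributedConv3d(Layer):
    """3D convolution with shared weights applied at every time step.

    Valid padding, isotropic stride.  Weights ``W[Cin, kx, ky, kz, Cout]``,
    bias ``b[Cout]``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int],
        stride: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.stride = stride
        rng = rng or np.random.default_rng(0)
        kvol = int(np.prod(self.kernel))
        self.params["W"] = glorot_uniform(
            (in_channels, *self.kernel, out_channels),
            fan_in=in_channels * kvol,
            fan_out=out_channels * kvol,
            rng=rng,
        )
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)
        self.zero_grads()

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: [N, X, Y, Z, C] -> [N, ox, oy, oz, C, kx, ky, kz]
        s = self.stride
        v = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=(1, 2, 3))
        return v[:, ::s, ::s, ::s]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 6:
            raise ShapeError(f"expected [B,T,X,Y,Z,C], got shape {x.shape}")
        b, t = x.shape[:2]
        spatial = x.shape[2:5]
        for n, k in zip(spatial, self.kernel):
            if n < k:
                raise ShapeError(f"kernel {self.kernel} larger than input spatial {spatial}")
        folded = x.reshape(b * t, *x.shape[2:])
        cols = np.ascontiguousarray(self._im2col(folded), dtype=DTYPE)
        n_out = cols.shape[0]
        out_spatial = cols.shape[1:4]
        # cols axes: [N, ox, oy, oz, C, kx, ky, kz]; flatten patch dims to match W
        colsf = cols.transpose(0, 1, 2, 3, 4, 5, 6, 7).reshape(
            n_out * int(np.prod(out_spatial)), -1
        )
        wmat = self.params["W"].reshape(-1, self.out_channels)
        y = colsf @ wmat + self.params["b"]
        self._cache = (x.shape, folded.shape, colsf, out_spatial)
        return y.reshape(b, t, *out_spatial, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, folded_shape, colsf, out_spatial = self._cache
        b, t = x_shape[:2]
        s = self.stride
        dyf = dy.reshape(-1, self.out_channels).astype(DTYPE)
        wmat = self.params["W"].reshape(-1, self.out_channels)
        self.grads["W"] += (colsf.T @ dyf).reshape(self.params["W"].shape)
        self.grads["b"] += dyf.sum(axis=0)
        dcols = (dyf @ wmat.T).reshape(
            b * t, *out_spatial, self.in_channels, *self.kernel
        )
        dx = np.zeros(folded_shape, dtype=DTYPE)
        ox, oy, oz = out_spatial
        kx, ky, kz = self.kernel
        for i, j, k in itertools.product(range(kx), range(ky), range(kz)):
            dx[:, i : i + s * ox : s, j : j + s * oy : s, k : k + s * oz : s, :] += dcols[
                :, :, :, :, :, i, j, k
            ]
        return dx.reshape(x_shape)


class BatchNorm(Layer):
    """Per-channel batch normalization over batch, time and space jointly."""

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.99) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels, dtype=DTYPE)
        self.params["beta"] = np.zeros(channels, dtype=DTYPE)
        # moving statistics: non-trainable, updated in training mode only
        self.moving_mean = np.zeros(channels, dtype=DTYPE)
        self.moving_var = np.ones(channels, dtype=DTYPE)
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.moving_mean = (
                self.momentum * self.moving_mean + (1.0 - self.momentum) * mean
            ).astype(DTYPE)
            self.moving_var = (
                self.momentum * self.moving_var + (1.0 - self.momentum) * var
            ).astype(DTYPE)
        else:
            mean, var = self.moving_mean, self.moving_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat.astype(DTYPE), inv_std.astype(DTYPE), axes, training)
        return (self.params["gamma"] * xhat + self.params["beta"]).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, training = self._cache
        self.grads["gamma"] += (dy * xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        g = self.params["gamma"]
        if not training:
            return (dy * g * inv_std).astype(DTYPE)
        m = float(np.prod([xhat.shape[a] for a in axes]))
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv_std
        return dx.astype(DTYPE)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(DTYPE)


class LSTM(Layer):
    """Single-direction LSTM over ``[B, T, D]`` with zero initial states.

    Gate order in the packed weight matrix is (f, i, g, o): forget, input,
    candidate, output.  One bias vector per gate (``4H`` entries total),
    weights ``W[D + H, 4H]`` acting on the concatenation ``[h_{t-1}, x_t]``.
    """

    def __init__(
        self,
        input_dim: int,
        hidden: int,
        reverse: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        self.input_dim = input_dim
        self.hidden = hidden
        self.reverse = reverse
        rng = rng or np.random.default_rng(0)
        self.params["W"] = glorot_uniform(
            (input_dim + hidden, 4 * hidden), fan_in=input_dim + hidden, fan_out=4 * hidden, rng=rng
        )
        self.params["b"] = np.zeros(4 * hidden, dtype=DTYPE)
        self.zero_grads()

    @staticmethod
    def step(
        x_t: np.ndarray,
        h_prev: np.ndarray,
        c_prev: np.ndarray,
        W: np.ndarray,
        b: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray, tuple]:
        """One recurrence step; returns (h_t, c_t, cache)."""
        h = h_prev.shape[-1]
        z = np.concatenate([h_prev, x_t], axis=-1) @ W + b
        f = sigmoid(z[..., :h])
        i = sigmoid(z[..., h : 2 * h])
        g = np.tanh(z[..., 2 * h : 3 * h])
        o = sigmoid(z[..., 3 * h :])
        c_t = f * c_prev + i * g
        tanh_c = np.tanh(c_t)
        h_t = o * tanh_c
        return h_t, c_t, (x_t, h_prev, c_prev, f, i, g, o, tanh_c)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 3 or x.shape[2] != self.input_dim:
            raise ShapeError(f"expected [B,T,{self.input_dim}], got {x.shape}")
        seq = x[:, ::-1] if self.reverse else x
        b, t, _ = seq.shape
        h = np.zeros((b, self.hidden), dtype=DTYPE)
        c = np.zeros((b, self.hidden), dtype=DTYPE)
        caches = []
        outs = np.empty((b, t, self.hidden), dtype=DTYPE)
        for step in range(t):
            h, c, cache = self.step(seq[:, step], h, c, self.params["W"], self.params["b"])
            outs[:, step] = h
            caches.append(cache)
        self._caches = caches
        return outs[:, ::-1] if self.reverse else outs

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.reverse:
            dy = dy[:, ::-1]
        b, t, h = dy.shape
        W = self.params["W"]
        dx_seq = np.zeros((b, t, self.input_dim), dtype=DTYPE)
        dh_next = np.zeros((b, h), dtype=DTYPE)
        dc_next = np.zeros((b, h), dtype=DTYPE)
        dW = np.zeros_like(W)
        db = np.zeros_like(self.params["b"])
        for step in range(t - 1, -1, -1):
            x_t, h_prev, c_prev, f, i, g, o, tanh_c = self._caches[step]
            dh = dy[:, step] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c**2) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    df * f * (1.0 - f),
                    di * i * (1.0 - i),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=-1,
            )
            concat = np.concatenate([h_prev, x_t], axis=-1)
            dW += concat.T @ dz
            db += dz.sum(axis=0)
            dconcat = dz @ W.T
            dh_next = dconcat[:, :h]
            dx_seq[:, step] = dconcat[:, h:]
        self.grads["W"] += dW
        self.grads["b"] += db
        return dx_seq[:, ::-1] if self.reverse else dx_seq


class BiLSTM(Layer):
    """Bidirectional LSTM: forward + reversed passes, outputs concatenated."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fwd = LSTM(input_dim, hidden, reverse=False, rng=rng)
        self.bwd = LSTM(input_dim, hidden, reverse=True, rng=rng)
        self.hidden = hidden
        for name, layer in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in layer.params.items():
                self.params[f"{name}_{k}"] = v
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._sync_in()
        return np.concatenate(
            [self.fwd.forward(x, training), self.bwd.forward(x, training)], axis=-1
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h = self.hidden
        dx = self.fwd.backward(dy[..., :h]) + self.bwd.backward(dy[..., h:])
        for name, layer in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k, v in layer.grads.items():
                self.grads[f"{name}_{k}"] += v
            layer.zero_grads()
        return dx

    def _sync_in(self) -> None:
        # params dict is the authority (the optimizer updates it in place or
        # replaces entries); push entries down to the two directions
        for name, layer in (("fwd", self.fwd), ("bwd", self.bwd)):
            for k in layer.params:
                layer.params[k] = self.params[f"{name}_{k}"]


class Dropout(Layer):
    """Inverted dropout; identity when inactive or rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ShapeError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return (x * self._mask).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(DTYPE)


class AdditiveAttention(Layer):
    """Learned softmax pooling over time: ``c = sum_j w_j h_j``.

    Scores ``s_j = u_a . tanh(W_a h_j + b_a)`` with a ``dim``-dimensional
    projection and learned context vector; ``w = softmax(s)`` over the time
    axis.  Collapses ``[B, T, D]`` to ``[B, D]``.
    """

    def __init__(self, input_dim: int, dim: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = glorot_uniform((input_dim, dim), input_dim, dim, rng)
        self.params["b"] = np.zeros(dim, dtype=DTYPE)
        self.params["u"] = glorot_uniform((dim,), dim, 1, rng)
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        u_proj = np.tanh(x @ self.params["W"] + self.params["b"])  # [B,T,dim]
        scores = u_proj @ self.params["u"]  # [B,T]
        w = softmax(scores, axis=1)
        ctx = np.einsum("bt,btd->bd", w, x)  # keeps the input's dtype
        self._cache = (x, u_proj, w)
        self.last_weights = w
        return ctx

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, u_proj, w = self._cache
        dw = np.einsum("bd,btd->bt", dy, x)
        dx = w[..., None] * dy[:, None, :]
        ds = w * (dw - (dw * w).sum(axis=1, keepdims=True))  # softmax jacobian
        du_proj = ds[..., None] * self.params["u"]
        self.grads["u"] += np.einsum("bt,btk->k", ds, u_proj)
        dpre = du_proj * (1.0 - u_proj**2)
        self.grads["W"] += np.einsum("btd,btk->dk", x, dpre)
        self.grads["b"] += dpre.sum(axis=(0, 1))
        dx += dpre @ self.params["W"].T
        return dx.astype(DTYPE)


class ElementwiseSoftmaxAttention(Layer):
    """Parameter-free literal pooling: per-feature softmax over time.

    ``w[t, d] = exp(h[t, d]) / sum_k exp(h[k, d])`` and
    ``c[d] = sum_t w[t, d] h[t, d]`` — the verbatim reading of an
    exponentiated hidden-state weighting, kept as a config switch.
    """

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        w = softmax(x, axis=1)
        self._cache = (x, w)
        self.last_weights = w
        return np.einsum("btd,btd->bd", w, x).astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, w = self._cache
        c = np.einsum("btd,btd->bd", w, x)
        # d c_d / d x_td = w_td * (1 + x_td - c_d)
        return (dy[:, None, :] * w * (1.0 + x - c[:, None, :])).astype(DTYPE)


class Dense(Layer):
    """Affine map ``y = x W + b`` with optional ReLU."""

    def __init__(
        self,
        input_dim: int,
        output_dim: int,
        relu: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["W"] = glorot_uniform((input_dim, output_dim), input_dim, output_dim, rng)
        self.params["b"] = np.zeros(output_dim, dtype=DTYPE)
        self.relu = relu
        self.zero_grads()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = x @ self.params["W"] + self.params["b"]
        if self.relu:
            self._cache = (x, y > 0)
            return np.where(y > 0, y, 0.0).astype(DTYPE)
        self._cache = (x, None)
        return y.astype(DTYPE)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, mask = self._cache
        if mask is not None:
            dy = np.where(mask, dy, 0.0)
        self.grads["W"] += x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return (dy @ self.params["W"].T).astype(DTYPE)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits.

    ``loss_i = -ln softmax(logits_i)[y_i]``, computed with the log-sum-exp
    trick so the log never sees a hard zero.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if logits.ndim == 1:
        logits = logits[None, :]
        labels = np.atleast_1d(labels)
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -log_probs[np.arange(n), labels].mean()
    probs = np.exp(log_probs)
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)
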