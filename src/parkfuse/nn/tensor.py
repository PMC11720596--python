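"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
records a closure that propagates the output gradient to its parents.
Only the operations required by the audio/lip encoders and the attention
fusion are provided.  Float inputs keep their dtype (tests may use
float64 for tight numeric comparisons); everything else is cast to
float32, which is what the models train in.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "stack",
    "relu",
    "sigmoid",
    "tanh",
    "softmax",
    "softmax_cross_entropy",
    "conv1d",
    "conv2d",
    "maxpool1d_pairs",
    "batchnorm",
    "dropout",
]


def _as_array(data) -> np.ndarray:
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    return arr


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(stack_.pop())
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
                # free intermediate gradients eagerly
                if node is not self:
                    node._backward = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(self.data + other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))

        def _bw():
            if self.requires_grad:
                self._accumulate(-out.grad)

        out._backward = _bw
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = _make(self.data * other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        return self * (1.0 / float(scalar))

    def __matmul__(self, other):
        out = _make(self.data @ other.data, (self, other))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = _bw
        return out

    def transpose(self, *axes):
        out = _make(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)

        def _bw():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(*inv))

        out._backward = _bw
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))

        def _bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                g[idx] = out.grad
                self._accumulate(g)

        out._backward = _bw
        return out

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def _bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    req = any(p.requires_grad for p in parents)
    out.requires_grad = req
    if req:
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


# -- joins -------------------------------------------------------------
def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(idx)])

    out._backward = _bw
    return out


def stack(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = _make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def _bw():
        gs = np.moveaxis(out.grad, axis, 0)
        for t, g in zip(tensors, gs):
            if t.requires_grad:
                t._accumulate(g)

    out._backward = _bw
    return out


# -- nonlinearities ----------------------------------------------------
def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0), (x,))

    def _bw():
        if x.requires_grad:
            x._accumulate(out.grad * (x.data > 0))

    out._backward = _bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(s, (x,))

    def _bw():
        if x.requires_grad:
            x._accumulate(out.grad * s * (1.0 - s))

    out._backward = _bw
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = _make(t, (x,))

    def _bw():
        if x.requires_grad:
            x._accumulate(out.grad * (1.0 - t * t))

    out._backward = _bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = _make(s, (x,))

    def _bw():
        if x.requires_grad:
            g = out.grad
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

    out._backward = _bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.data.shape[0]
    loss = -logp[np.arange(n), labels].mean()
    out = _make(np.asarray(loss, dtype=logits.data.dtype), (logits,))

    def _bw():
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accumulate(out.grad * p / n)

    out._backward = _bw
    return out


# -- structured ops ----------------------------------------------------
def _im2col1d(x: np.ndarray, kernel: int, stride: int) -> np.ndarray:
    n, cin, length = x.shape
    lp = (length - kernel) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=2)[:, :, ::stride]
    return view.transpose(0, 2, 1, 3).reshape(n * lp, cin * kernel), lp


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int) -> Tensor:
    """Valid (no padding) strided cross-correlation along the last axis.

    ``x``: (N, C_in, L); ``w``: (C_out, C_in, K); output (N, C_out, L')
    with L' = floor((L - K)/stride) + 1.
    """
    n, cin, length = x.data.shape
    cout, cin2, kernel = w.data.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin2}")
    if length < kernel:
        raise ValueError(f"input length {length} shorter than kernel {kernel}")
    cols, lp = _im2col1d(x.data, kernel, stride)
    y = cols @ w.data.reshape(cout, cin * kernel).T + b.data
    out = _make(y.reshape(n, lp, cout).transpose(0, 2, 1), (x, w, b))

    def _bw():
        g = out.grad.transpose(0, 2, 1).reshape(n * lp, cout)
        if w.requires_grad:
            cols2, _ = _im2col1d(x.data, kernel, stride)  # recomputed: cheaper than holding it
            w._accumulate((g.T @ cols2).reshape(cout, cin, kernel))
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if x.requires_grad:
            gcols = (g @ w.data.reshape(cout, cin * kernel)).reshape(n, lp, cin, kernel)
            gx = np.zeros_like(x.data)
            for k in range(kernel):
                gx[:, :, k : k + stride * lp : stride] += gcols[:, :, :, k].transpose(0, 2, 1)
            x._accumulate(gx)

    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """Strided 2-D cross-correlation with symmetric zero padding.

    ``x``: (N, C_in, H, W); ``w``: (C_out, C_in, kH, kW).
    """
    n, cin, h, wd = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin2}")
    xp = x.data
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (xp.shape[2] - kh) // stride + 1
    wo = (xp.shape[3] - kw) // stride + 1

    def _cols(arr):
        view = np.lib.stride_tricks.sliding_window_view(arr, (kh, kw), axis=(2, 3))
        view = view[:, :, ::stride, ::stride]
        return view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, cin * kh * kw)

    y = _cols(xp) @ w.data.reshape(cout, -1).T + b.data
    out = _make(y.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2), (x, w, b))

    def _bw():
        g = out.grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
        if w.requires_grad:
            xp2 = xp  # padded copy kept alive by closure only when grads are needed
            w._accumulate((g.T @ _cols(xp2)).reshape(cout, cin, kh, kw))
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if x.requires_grad:
            gcols = (g @ w.data.reshape(cout, -1)).reshape(n, ho, wo, cin, kh, kw)
            gp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            if padding:
                gp = gp[:, :, padding:-padding, padding:-padding]
            x._accumulate(gp)

    out._backward = _bw
    return out


def maxpool1d_pairs(x: Tensor) -> Tensor:
    """Non-overlapping temporal max pooling with kernel = stride = 2."""
    n, c, length = x.data.shape
    lp = length // 2
    trimmed = x.data[:, :, : 2 * lp].reshape(n, c, lp, 2)
    arg = trimmed.argmax(axis=3)
    out = _make(np.take_along_axis(trimmed, arg[..., None], axis=3)[..., 0], (x,))

    def _bw():
        g = np.zeros((n, c, lp, 2), dtype=x.data.dtype)
        np.put_along_axis(g, arg[..., None], out.grad[..., None], axis=3)
        gx = np.zeros_like(x.data)
        gx[:, :, : 2 * lp] = g.reshape(n, c, 2 * lp)
        x._accumulate(gx)

    out._backward = _bw if x.requires_grad else None
    return out


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over all axes except channel axis 1.

    ``running_mean``/``running_var`` are updated in place in training mode.
    """
    axes = tuple(i for i in range(x.data.ndim) if i != 1)
    shape = [1] * x.data.ndim
    shape[1] = x.data.shape[1]
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size // x.data.shape[1]
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu = running_mean
        var = running_var
    ivstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * ivstd.reshape(shape)
    out = _make(gamma.data.reshape(shape) * xhat + beta.data.reshape(shape), (x, gamma, beta))

    def _bw():
        g = out.grad
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(shape)
            if training:
                m = x.data.size // x.data.shape[1]
                s1 = gxhat.sum(axis=axes, keepdims=True)
                s2 = (gxhat * xhat).sum(axis=axes, keepdims=True)
                gx = (ivstd.reshape(shape) / m) * (m * gxhat - s1 - xhat * s2)
            else:
                gx = gxhat * ivstd.reshape(shape)
            x._accumulate(gx)

    out._backward = _bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    out = _make(x.data * mask, (x,))

    def _bw():
        if x.requires_grad:
            x._accumulate(out.grad * mask)

    out._backward = _bw
    return out
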