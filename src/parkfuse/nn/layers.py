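"""Neural layers built on the autograd engine: linear, convolutional,
batch-norm and a bidirectional multi-layer LSTM."""

from __future__ import annotations

import numpy as np

from .tensor import (
    Tensor,
    batchnorm,
    concat,
    conv1d,
    conv2d,
    sigmoid,
    stack,
    tanh,
)

__all__ = ["Module", "Linear", "Conv1d", "Conv2d", "BatchNorm", "LSTM"]


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Tensor) and item.requires_grad and id(item) not in seen:
                    seen.add(id(item))
                    params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Module):
                    out.extend(item.modules())
        return out

    def buffers(self) -> list[np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        out = []
        for m in self.modules():
            for name in ("running_mean", "running_var"):
                buf = getattr(m, name, None)
                if isinstance(buf, np.ndarray):
                    out.append(buf)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}
        state.update({f"b{i}": b.copy() for i, b in enumerate(self.buffers())})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        buffers = self.buffers()
        if len(state) != len(params) + len(buffers):
            raise ValueError("state does not match model parameters")
        for i, p in enumerate(params):
            p.data = state[f"p{i}"].astype(p.data.dtype).copy()
        for i, b in enumerate(buffers):
            b[...] = state[f"b{i}"]


def _param(arr: np.ndarray) -> Tensor:
    t = Tensor(arr.astype(np.float32))
    t.requires_grad = True
    return t


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = _param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = _param(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.weight = _param(rng.normal(0.0, scale, size=(c_out, c_in, kernel)))
        self.bias = _param(np.zeros(c_out))
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, self.stride)


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int,
        padding: int,
        rng: np.random.Generator,
    ):
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.weight = _param(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)))
        self.bias = _param(np.zeros(c_out))
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm(Module):
    """Channel-wise batch normalization for (N, C, ...) tensors."""

    def __init__(self, channels: int):
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return batchnorm(x, self.gamma, self.beta, self.running_mean, self.running_var, training)


class _LSTMCellParams(Module):
    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden)
        self.wx = _param(rng.uniform(-k, k, size=(n_in, 4 * hidden)))
        self.wh = _param(rng.uniform(-k, k, size=(hidden, 4 * hidden)))
        self.bias = _param(np.zeros(4 * hidden))
        self.hidden = hidden


class LSTM(Module):
    """Multi-layer bidirectional LSTM over (N, T, C) sequences.

    Output width is ``2 * hidden`` (forward/backward concatenated per step).
    """

    def __init__(self, n_in: int, hidden: int, num_layers: int, rng: np.random.Generator):
        self.hidden = hidden
        self.num_layers = num_layers
        self.cells: list[_LSTMCellParams] = []
        width = n_in
        for _ in range(num_layers):
            self.cells.append(_LSTMCellParams(width, hidden, rng))  # forward
            self.cells.append(_LSTMCellParams(width, hidden, rng))  # backward
            width = 2 * hidden

    def _run_direction(self, x: Tensor, cell: _LSTMCellParams, reverse: bool) -> list[Tensor]:
        n, t, _ = x.shape
        h_dim = cell.hidden
        h = Tensor(np.zeros((n, h_dim), dtype=x.data.dtype))
        c = Tensor(np.zeros((n, h_dim), dtype=x.data.dtype))
        order = range(t - 1, -1, -1) if reverse else range(t)
        outs: dict[int, Tensor] = {}
        for step in order:
            xt = x[:, step, :]
            gates = xt @ cell.wx + h @ cell.wh + cell.bias
            i = sigmoid(gates[:, :h_dim])
            f = sigmoid(gates[:, h_dim : 2 * h_dim])
            g = tanh(gates[:, 2 * h_dim : 3 * h_dim])
            o = sigmoid(gates[:, 3 * h_dim :])
            c = f * c + i * g
            h = o * tanh(c)
            outs[step] = h
        return [outs[step] for step in range(t)]

    def __call__(self, x: Tensor) -> Tensor:
        seq = x
        for layer in range(self.num_layers):
            fwd = self._run_direction(seq, self.cells[2 * layer], reverse=False)
            bwd = self._run_direction(seq, self.cells[2 * layer + 1], reverse=True)
            steps = [concat([f, b], axis=1) for f, b in zip(fwd, bwd)]
            seq = stack(steps, axis=1)
        return seq
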