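"""Autograd core tests: structured ops against brute-force oracles and
finite-difference gradient checks."""

import numpy as np
import pytest

from parkfuse import nn
from parkfuse.nn import Tensor


def _tensor(rng, *shape, grad=True):
    t = Tensor(rng.standard_normal(shape))  # float64 for tight checks
    t.requires_grad = grad
    return t


def _numerical_grad(f, t, eps=1e-6):
    g = np.zeros_like(t.data)
    it = np.nditer(t.data, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = t.data[i]
        t.data[i] = orig + eps
        up = float(f().data)
        t.data[i] = orig - eps
        down = float(f().data)
        t.data[i] = orig
        g[i] = (up - down) / (2 * eps)
        it.iternext()
    return g


def _check_grads(f, params, tol=5e-4):
    for p in params:
        p.zero_grad()
    f().backward()
    for p in params:
        numeric = _numerical_grad(f, p)
        scale = np.abs(numeric).max() + 1e-8
        assert np.abs(numeric - p.grad).max() / scale < tol


class TestConv1d:
    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        x = _tensor(rng, 1, 1, 100, grad=False)
        w = _tensor(rng, 3, 1, 7, grad=False)
        b = _tensor(rng, 3, grad=False)
        stride = 2
        out = nn.conv1d(x, w, b, stride).data
        l_out = (100 - 7) // stride + 1
        expected = np.zeros((1, 3, l_out))
        for co in range(3):
            for i in range(l_out):
                acc = b.data[co]
                for k in range(7):
                    acc += w.data[co, 0, k] * x.data[0, 0, i * stride + k]
                expected[0, co, i] = acc
        assert np.abs(out - expected).max() < 1e-9

    @pytest.mark.parametrize(
        "length,kernel,stride,expected",
        [(48_000, 480, 12, 3961), (1980, 240, 6, 291)],
    )
    def test_output_length_arithmetic(self, length, kernel, stride, expected):
        rng = np.random.default_rng(1)
        x = Tensor(np.zeros((1, 1, length), dtype=np.float32))
        w = Tensor(np.zeros((1, 1, kernel), dtype=np.float32))
        b = Tensor(np.zeros(1, dtype=np.float32))
        assert nn.conv1d(x, w, b, stride).shape == (1, 1, expected)

    def test_identity_kernel_shifts_input(self):
        x = Tensor(np.arange(10.0).reshape(1, 1, 10))
        w = Tensor(np.array([[[0.0, 0.0, 1.0]]]))
        b = Tensor(np.zeros(1))
        out = nn.conv1d(x, w, b, 1).data[0, 0]
        assert np.array_equal(out, np.arange(2.0, 10.0))

    def test_input_shorter_than_kernel_rejected(self):
        x = Tensor(np.zeros((1, 1, 5)))
        w = Tensor(np.zeros((1, 1, 10)))
        with pytest.raises(ValueError):
            nn.conv1d(x, w, Tensor(np.zeros(1)), 1)

    def test_gradients(self):
        rng = np.random.default_rng(2)
        x = _tensor(rng, 2, 2, 15)
        w = _tensor(rng, 3, 2, 4)
        b = _tensor(rng, 3)
        _check_grads(lambda: nn.conv1d(x, w, b, 2).sum(), [x, w, b])


class TestConv2d:
    def test_gradients_with_stride_and_padding(self):
        rng = np.random.default_rng(3)
        x = _tensor(rng, 2, 2, 6, 7)
        w = _tensor(rng, 3, 2, 3, 3)
        b = _tensor(rng, 3)
        _check_grads(lambda: nn.conv2d(x, w, b, 2, 1).sum(), [x, w, b])

    def test_spatial_arithmetic_ceil_division(self):
        x = Tensor(np.zeros((1, 1, 50, 100), dtype=np.float32))
        w = Tensor(np.zeros((1, 1, 3, 3), dtype=np.float32))
        b = Tensor(np.zeros(1, dtype=np.float32))
        assert nn.conv2d(x, w, b, 2, 1).shape == (1, 1, 25, 50)


class TestPoolingAndNorm:
    def test_maxpool_matches_pairwise_oracle(self):
        rng = np.random.default_rng(4)
        x = Tensor(rng.standard_normal((2, 3, 11)))
        out = nn.maxpool1d_pairs(x).data
        expected = np.maximum(x.data[:, :, 0:10:2], x.data[:, :, 1:10:2])
        assert np.array_equal(out, expected)

    def test_maxpool_monotone_input_keeps_later_element(self):
        x = Tensor(np.arange(8.0).reshape(1, 1, 8))
        assert np.array_equal(nn.maxpool1d_pairs(x).data[0, 0], [1.0, 3.0, 5.0, 7.0])

    def test_maxpool_gradients(self):
        rng = np.random.default_rng(5)
        x = _tensor(rng, 2, 2, 9)
        weights = Tensor(rng.standard_normal((2, 2, 4)))
        _check_grads(lambda: (nn.maxpool1d_pairs(x) * weights).sum(), [x])

    def test_batchnorm_gradients(self):
        rng = np.random.default_rng(6)
        x = _tensor(rng, 4, 3, 5)
        gamma = _tensor(rng, 3)
        beta = _tensor(rng, 3)
        weights = Tensor(rng.standard_normal((4, 3, 5)))

        def f():
            rm, rv = np.zeros(3), np.ones(3)
            return (nn.batchnorm(x, gamma, beta, rm, rv, True) * weights).sum()

        _check_grads(f, [x, gamma, beta])

    def test_batchnorm_normalizes_training_batch(self):
        rng = np.random.default_rng(7)
        x = Tensor(rng.standard_normal((8, 4, 10)) * 3 + 2)
        out = nn.batchnorm(x, Tensor(np.ones(4)), Tensor(np.zeros(4)), np.zeros(4), np.ones(4), True)
        assert np.abs(out.data.mean(axis=(0, 2))).max() < 1e-6
        assert np.abs(out.data.std(axis=(0, 2)) - 1).max() < 1e-3


class TestSoftmaxAndLstm:
    def test_softmax_rows_stochastic_for_any_logits(self):
        rng = np.random.default_rng(8)
        logits = Tensor(rng.standard_normal((5, 7)) * 50)
        s = nn.softmax(logits, axis=-1).data
        assert np.allclose(s.sum(axis=-1), 1.0)
        assert np.all(s >= 0)

    def test_cross_entropy_gradients(self):
        rng = np.random.default_rng(9)
        logits = _tensor(rng, 6, 2)
        labels = np.array([0, 1, 1, 0, 1, 0])
        _check_grads(lambda: nn.softmax_cross_entropy(logits, labels), [logits])

    def test_lstm_output_width_and_gradients(self):
        rng = np.random.default_rng(10)
        lstm = nn.LSTM(3, 4, 2, rng)
        for p in lstm.parameters():
            p.data = p.data.astype(np.float64)
        x = _tensor(rng, 2, 5, 3)
        out = lstm(x)
        assert out.shape == (2, 5, 8)
        weights = Tensor(rng.standard_normal((2, 5, 8)))
        _check_grads(lambda: (lstm(x) * weights).sum(), [x] + lstm.parameters()[:2])


class TestTraining:
    def test_checkpoint_roundtrip_includes_norm_buffers(self):
        rng = np.random.default_rng(11)
        bn = nn.BatchNorm(3)
        x = Tensor(rng.standard_normal((4, 3, 5)))
        bn(x, training=True)
        state = bn.state_dict()
        bn(Tensor(rng.standard_normal((4, 3, 5)) * 10), training=True)
        changed = bn.running_mean.copy()
        bn.load_state_dict(state)
        assert not np.allclose(bn.running_mean, changed)
        assert np.allclose(bn.state_dict()["b0"], state["b0"])

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(12)

        class Linear2(nn.Module):
            def __init__(self):
                self.lin = nn.Linear(4, 2, rng)

            def forward_logits(self, x, training=False):
                return self.lin(Tensor(x))

        X = rng.standard_normal((8, 4)).astype(np.float32)
        with pytest.raises(ValueError):
            nn.fit_classifier(Linear2(), (X,), np.zeros(8, dtype=int), (X,), np.zeros(8, dtype=int), nn.TrainConfig(epochs=1))

    def test_early_stopping_halts_on_stale_validation(self):
        rng = np.random.default_rng(13)

        class Frozen(nn.Module):
            """Output independent of input: validation can never improve."""

            def __init__(self):
                self.lin = nn.Linear(4, 2, rng)

            def forward_logits(self, x, training=False):
                return self.lin(Tensor(np.zeros_like(x)))

        X = rng.standard_normal((16, 4)).astype(np.float32)
        y = np.tile([0, 1], 8)
        hist = nn.fit_classifier(
            Frozen(), (X,), y, (X,), y, nn.TrainConfig(epochs=50, patience=3, seed=0)
        )
        assert len(hist.epochs) < 50
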