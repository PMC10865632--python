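"""Minimal NumPy neural-network engine for the temporal-convolutional detector.

Implements exactly the pieces the detector needs - dilated 1-D convolutions
with symmetric zero padding, residual layers with ReLU and dropout, softmax,
and Adam - with hand-written backward passes.  Sequences are processed whole
(shape ``(channels, T)``); there is no batching dimension because the model
is fully convolutional and trials have heterogeneous lengths.

All computation is float32.  Given a seeded ``numpy.random.Generator`` for
initialization and dropout, training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1d", "DilatedResidualLayer", "Stage", "MultiStageTCN", "Adam", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Column-wise softmax of a (classes, T) logit array."""
    m = logits.max(axis=0, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=0, keepdims=True)


def softmax_backward(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Gradient through softmax: given dL/dp, return dL/dlogits."""
    return p * (dp - (dp * p).sum(axis=0, keepdims=True))


class Conv1d:
    """1-D convolution over (C_in, T) -> (C_out, T), symmetric zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        dilation: int,
        rng: np.random.Generator,
    ):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for symmetric padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        std = np.sqrt(2.0 / (in_channels * kernel_size))
        # weight laid out tap-major for a single-GEMM forward pass
        self.W = rng.normal(0.0, std, size=(out_channels, kernel_size * in_channels)).astype(
            np.float32
        )
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xcol: np.ndarray | None = None
        self._T: int = 0

    @property
    def pad(self) -> int:
        return self.dilation * (self.kernel_size - 1) // 2

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        C, T = x.shape
        k, d, pad = self.kernel_size, self.dilation, self.pad
        if k == 1:
            return x
        xp = np.zeros((C, T + 2 * pad), dtype=np.float32)
        xp[:, pad : pad + T] = x
        cols = np.empty((k * C, T), dtype=np.float32)
        for tap in range(k):
            cols[tap * C : (tap + 1) * C] = xp[:, tap * d : tap * d + T]
        return cols

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xcol = self._im2col(x)
        if train:
            self._xcol = xcol
            self._T = x.shape[1]
        return self.W @ xcol + self.b[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._xcol is not None, "forward(train=True) must precede backward"
        self.db += dy.sum(axis=1)
        self.dW += dy @ self._xcol.T
        dxcol = self.W.T @ dy
        k, d, pad, C, T = self.kernel_size, self.dilation, self.pad, self.in_channels, self._T
        if k == 1:
            return dxcol
        dxp = np.zeros((C, T + 2 * pad), dtype=np.float32)
        for tap in range(k):
            dxp[:, tap * d : tap * d + T] += dxcol[tap * C : (tap + 1) * C]
        return dxp[:, pad : pad + T]

    def params(self):
        yield self

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0


class DilatedResidualLayer:
    """x + Conv1x1(ReLU(DilatedConv(x))) with optional inverted dropout."""

    def __init__(self, filters: int, kernel_size: int, dilation: int, dropout: float,
                 rng: np.random.Generator):
        self.conv_dilated = Conv1d(filters, filters, kernel_size, dilation, rng)
        self.conv_1x1 = Conv1d(filters, filters, 1, 1, rng)
        self.dropout = dropout
        self._relu_mask: np.ndarray | None = None
        self._drop_mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h = self.conv_dilated.forward(x, train)
        mask = h > 0
        h *= mask
        if train:
            self._relu_mask = mask
        h = self.conv_1x1.forward(h, train)
        if train and self.dropout > 0.0:
            keep = (rng.random(h.shape) >= self.dropout).astype(np.float32)
            keep /= 1.0 - self.dropout
            h *= keep
            self._drop_mask = keep
        else:
            self._drop_mask = None
        return x + h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dh = dout if self._drop_mask is None else dout * self._drop_mask
        dh = self.conv_1x1.backward(dh)
        dh *= self._relu_mask
        dx = self.conv_dilated.backward(dh)
        return dout + dx

    def params(self):
        yield from self.conv_dilated.params()
        yield from self.conv_1x1.params()


class Stage:
    """One prediction stage: 1x1 in, dilated residual tower (doubling
    dilations), 1x1 out to class logits."""

    def __init__(self, in_channels: int, n_classes: int, n_layers: int, filters: int,
                 kernel_size: int, dropout: float, rng: np.random.Generator):
        self.conv_in = Conv1d(in_channels, filters, 1, 1, rng)
        self.layers = [
            DilatedResidualLayer(filters, kernel_size, 2**i, dropout, rng)
            for i in range(n_layers)
        ]
        self.conv_out = Conv1d(filters, n_classes, 1, 1, rng)
        self.kernel_size = kernel_size
        self.n_layers = n_layers

    @property
    def receptive_field(self) -> int:
        return 1 + (self.kernel_size - 1) * sum(2**i for i in range(self.n_layers))

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        h = self.conv_in.forward(x, train)
        for layer in self.layers:
            h = layer.forward(h, train, rng)
        return self.conv_out.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dh = self.conv_out.backward(dlogits)
        for layer in reversed(self.layers):
            dh = layer.backward(dh)
        return self.conv_in.backward(dh)

    def params(self):
        yield from self.conv_in.params()
        for layer in self.layers:
            yield from layer.params()
        yield from self.conv_out.params()


class MultiStageTCN:
    """Initial prediction stage over raw channels plus refinement stages that
    consume and re-emit per-sample class probabilities."""

    def __init__(self, in_channels: int, n_classes: int,
                 initial_layers: int, initial_filters: int,
                 n_refinement_stages: int, refinement_layers: int, refinement_filters: int,
                 kernel_size: int, dropout: float, rng: np.random.Generator):
        if n_refinement_stages < 1:
            raise ValueError("at least one refinement stage is required")
        self.stages = [
            Stage(in_channels, n_classes, initial_layers, initial_filters,
                  kernel_size, dropout, rng)
        ]
        for _ in range(n_refinement_stages):
            self.stages.append(
                Stage(n_classes, n_classes, refinement_layers, refinement_filters,
                      kernel_size, dropout, rng)
            )
        self._probs: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> list[np.ndarray]:
        """Return per-stage logits, each of shape (n_classes, T)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        logits_list = []
        self._probs = []
        h = x
        for stage in self.stages:
            logits = stage.forward(h, train, rng)
            logits_list.append(logits)
            p = softmax(logits)
            self._probs.append(p)
            h = p
        return logits_list

    def backward(self, dlogits_list: list[np.ndarray]) -> None:
        """Backpropagate per-stage logit gradients, chaining through the
        probability inputs of the downstream stages."""
        carry = None  # dL/d(input probs of the next stage)
        for s in range(len(self.stages) - 1, -1, -1):
            dlogits = dlogits_list[s].astype(np.float32)
            if carry is not None:
                dlogits = dlogits + softmax_backward(self._probs[s], carry)
            carry = self.stages[s].backward(dlogits)

    def params(self):
        for stage in self.stages:
            yield from stage.params()

    def zero_grad(self) -> None:
        for conv in self.params():
            conv.zero_grad()

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, conv in enumerate(self.params()):
            out[f"W{i}"] = conv.W
            out[f"b{i}"] = conv.b
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, conv in enumerate(self.params()):
            conv.W = state[f"W{i}"].astype(np.float32)
            conv.b = state[f"b{i}"].astype(np.float32)


class Adam:
    """Adam over the convolution parameters of a model."""

    def __init__(self, model: MultiStageTCN, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.convs = list(model.params())
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.mW = [np.zeros_like(c.W) for c in self.convs]
        self.vW = [np.zeros_like(c.W) for c in self.convs]
        self.mb = [np.zeros_like(c.b) for c in self.convs]
        self.vb = [np.zeros_like(c.b) for c in self.convs]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for i, c in enumerate(self.convs):
            for g, p, m, v in ((c.dW, c.W, self.mW[i], self.vW[i]),
                               (c.db, c.b, self.mb[i], self.vb[i])):
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)
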