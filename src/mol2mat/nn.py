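"""Compact numpy engine for the fused convolutional classifier.

Implements exactly the layer vocabulary the architecture needs — unpadded 3x3
convolution (via im2col so the inner loop is a BLAS matmul), 2x2 max-pooling,
dense layers, ReLU, softmax with categorical cross-entropy, and Adam — with
reverse-mode gradients.  Everything is float32 and driven by a single
``numpy.random.Generator``, so training is bit-reproducible from a seed on a
fixed platform.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .architecture import FusedArchitectureSpec

__all__ = ["FusedCNN", "instantiate_model", "softmax", "cross_entropy"]

_DT = np.float32


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    return float(-(onehot * np.log(probs + eps)).sum(axis=1).mean())


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*OH*OW, C*k*k) patch matrix for a valid convolution."""
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N, C, OH, OW, k, k)
    n, c, oh, ow, _, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * oh * ow, c * k * k)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int) -> np.ndarray:
    """Scatter-add the patch-matrix gradient back onto the input."""
    n, c, h, w = x_shape
    oh, ow = h - k + 1, w - k + 1
    d = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + oh, j : j + ow] += d[:, :, :, :, i, j]
    return dx


class _Conv3x3:
    """Valid 3x3 convolution, stride 1, He-initialised."""

    K = 3

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        fan_in = in_ch * self.K * self.K
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, fan_in)).astype(_DT)
        self.b = np.zeros(out_ch, dtype=_DT)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        self._cols = _im2col(x, self.K)
        n, _, h, w = x.shape
        oh, ow = h - self.K + 1, w - self.K + 1
        out = self._cols @ self.W.T + self.b
        return out.reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, f, oh, ow = dout.shape
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, f)
        self.dW = dmat.T @ self._cols
        self.db = dmat.sum(axis=0)
        return _col2im(dmat @ self.W, self._x_shape, self.K)

    def params(self):
        return [("W", self), ("b", self)]


class _MaxPool2x2:
    """2x2 max-pool, stride 2; an odd trailing row/column is dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        self._x_shape = x.shape
        windows = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        windows = windows.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = windows.argmax(axis=-1)
        return np.take_along_axis(windows, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        h2, w2 = h // 2, w // 2
        dwin = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            dwin.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(_DT)
        self.b = np.zeros(n_out, dtype=_DT)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T


class _Adam:
    """Adaptive-moment optimiser over a flat list of (layer, attr) slots."""

    def __init__(self, slots, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.slots = slots
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(layer, attr)) for layer, attr in slots]
        self.v = [np.zeros_like(getattr(layer, attr)) for layer, attr in slots]

    def step(self):
        self.t += 1
        for i, (layer, attr) in enumerate(self.slots):
            g = getattr(layer, "d" + attr)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            setattr(layer, attr, getattr(layer, attr) - self.lr * mhat / (np.sqrt(vhat) + self.eps))


class _Branch:
    """conv(3x3) -> ReLU -> conv(3x3) -> ReLU -> pool(2x2) -> flatten."""

    def __init__(self, channels: tuple[int, int], rng: np.random.Generator):
        self.conv1 = _Conv3x3(1, channels[0], rng)
        self.relu1 = _ReLU()
        self.conv2 = _Conv3x3(channels[0], channels[1], rng)
        self.relu2 = _ReLU()
        self.pool = _MaxPool2x2()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x))
        h = self.relu2.forward(self.conv2.forward(h))
        h = self.pool.forward(h)
        self._out_shape = h.shape
        return h.reshape(h.shape[0], -1)

    def backward(self, dflat: np.ndarray) -> None:
        d = self.pool.backward(dflat.reshape(self._out_shape))
        d = self.conv2.backward(self.relu2.backward(d))
        self.conv1.backward(self.relu1.backward(d))

    def slots(self):
        return [(self.conv1, "W"), (self.conv1, "b"), (self.conv2, "W"), (self.conv2, "b")]


class FusedCNN:
    """The instantiated fused model: k convolutional branches, feature
    concatenation, two ReLU dense layers and a softmax output.

    Inputs are a list of k arrays of shape (N, n_i, n_i), one per branch, in
    branch order.  ``predict_proba`` rows sum to 1.
    """

    def __init__(self, spec: FusedArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.branches = [_Branch(b.channels, rng) for b in spec.branches]
        cw = spec.concat_width
        self.dense1 = _Dense(cw, spec.dense_1, rng)
        self.relu1 = _ReLU()
        self.dense2 = _Dense(spec.dense_1, spec.dense_2, rng)
        self.relu2 = _ReLU()
        self.out = _Dense(spec.dense_2, spec.n_classes, rng)

    # -- introspection ------------------------------------------------------

    @property
    def concat_width(self) -> int:
        """Width of the concatenation layer, read off the first dense weight."""
        return self.dense1.W.shape[0]

    def introspect(self) -> dict:
        """Layer widths as actually instantiated (from weight shapes)."""
        return {
            "n_branches": len(self.branches),
            "branch_flatten_widths": [b.flatten_width for b in self.spec.branches],
            "concat_width": self.concat_width,
            "dense_1": self.dense1.W.shape[1],
            "dense_2": self.dense2.W.shape[1],
            "n_classes": self.out.W.shape[1],
        }

    def state_dict(self) -> dict:
        """Named parameter arrays, suitable for ``numpy.savez``."""
        return {f"p{i}": getattr(layer, attr) for i, (layer, attr) in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        for i, (layer, attr) in enumerate(self.parameters()):
            arr = np.asarray(state[f"p{i}"], dtype=_DT)
            if arr.shape != getattr(layer, attr).shape:
                raise ValueError(f"shape mismatch for parameter p{i}")
            setattr(layer, attr, arr)

    def parameters(self):
        slots = []
        for br in self.branches:
            slots.extend(br.slots())
        slots.extend(
            [(self.dense1, "W"), (self.dense1, "b"), (self.dense2, "W"), (self.dense2, "b"),
             (self.out, "W"), (self.out, "b")]
        )
        return slots

    # -- forward / backward -------------------------------------------------

    def _check_inputs(self, xs) -> list[np.ndarray]:
        if len(xs) != len(self.branches):
            raise ValueError(f"expected {len(self.branches)} branch inputs, got {len(xs)}")
        out = []
        for x, bspec in zip(xs, self.spec.branches):
            x = np.asarray(x, dtype=_DT)
            if x.ndim != 3 or x.shape[1:] != (bspec.input_side, bspec.input_side):
                raise ValueError(
                    f"branch input must be (N, {bspec.input_side}, {bspec.input_side}), got {x.shape}"
                )
            out.append(x[:, None, :, :])  # add channel axis
        return out

    def forward(self, xs) -> np.ndarray:
        xs = self._check_inputs(xs)
        feats = [br.forward(x) for br, x in zip(self.branches, xs)]
        self._split = np.cumsum([f.shape[1] for f in feats])[:-1]
        concat = np.concatenate(feats, axis=1)
        h = self.relu1.forward(self.dense1.forward(concat))
        h = self.relu2.forward(self.dense2.forward(h))
        self._probs = softmax(self.out.forward(h))
        return self._probs

    def backward(self, onehot: np.ndarray) -> None:
        # combined softmax + cross-entropy gradient
        d = (self._probs - onehot.astype(_DT)) / onehot.shape[0]
        d = self.out.backward(d)
        d = self.dense2.backward(self.relu2.backward(d))
        d = self.dense1.backward(self.relu1.backward(d))
        for br, dpart in zip(self.branches, np.split(d, self._split, axis=1)):
            br.backward(dpart)

    def predict_proba(self, xs, batch_size: int = 256) -> np.ndarray:
        n = np.asarray(xs[0]).shape[0]
        out = np.empty((n, self.spec.n_classes), dtype=_DT)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            out[sl] = self.forward([x[sl] for x in xs])
        return out

    # -- training -----------------------------------------------------------

    def fit(
        self,
        xs,
        onehot: np.ndarray,
        epochs: int = 20,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
        validation: tuple | None = None,
    ) -> list[dict]:
        """Minimise categorical cross-entropy by minibatch Adam.

        Returns one record per epoch with training accuracy and MSE (between
        one-hot targets and softmax probabilities), plus validation figures
        when a ``(xs_val, onehot_val)`` pair is given.  Raises on a non-finite
        loss, reporting the epoch.
        """
        n = onehot.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        onehot = onehot.astype(_DT)
        rng = np.random.default_rng(seed)
        optim = _Adam(self.parameters(), lr=lr)
        history = []
        for epoch in range(1, epochs + 1):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                probs = self.forward([x[idx] for x in xs])
                loss = cross_entropy(probs, onehot[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
                self.backward(onehot[idx])
                optim.step()
            record = {"epoch": epoch, **self._epoch_metrics(xs, onehot, "")}
            if validation is not None:
                record.update(self._epoch_metrics(validation[0], validation[1], "val_"))
            history.append(record)
        return history

    def _epoch_metrics(self, xs, onehot, prefix: str) -> dict:
        probs = self.predict_proba(xs)
        acc = float((probs.argmax(axis=1) == onehot.argmax(axis=1)).mean())
        mse = float(((probs - onehot) ** 2).mean())
        return {prefix + "accuracy": acc, prefix + "mse": mse}


def instantiate_model(spec: FusedArchitectureSpec, seed: int = 0) -> FusedCNN:
    """Build a trainable fused CNN from its architecture spec; parameter
    initialisation is reproducible from the seed."""
    return FusedCNN(spec, seed=seed)
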