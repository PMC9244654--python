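"""Smoke-scale neural classifiers on the package's numpy autograd.

Two sklearn-compatible binary classifiers back the deep-learning model
families: a residual convolutional network over the zero-padded 42x42
feature image, and an LSTM over per-visit event sequences.  Both run at
reduced width/depth by definition — they exercise the input-reshaping
conventions and the evaluation harness, not large-scale training.
"""

from __future__ import annotations

import functools

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .autograd import Adam, Tensor, parameter


@functools.lru_cache(maxsize=32)
def _conv_index(C, Hp, Wp, kh, kw, stride):
    """im2col gather index over a flattened (C, Hp, Wp) layout."""
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    c, i, j = np.meshgrid(np.arange(C), np.arange(kh), np.arange(kw), indexing="ij")
    cell = (c * Hp * Wp + i * Wp + j).ravel()  # (C*kh*kw,)
    oh, ow = np.meshgrid(np.arange(OH), np.arange(OW), indexing="ij")
    origin = (oh * stride * Wp + ow * stride).ravel()  # (OH*OW,)
    return origin[:, None] + cell[None, :], OH, OW


def _conv2d(x: Tensor, chw, weight: Tensor, bias: Tensor, stride=1, pad=1, k=3):
    """3x3 convolution on a flat (N, C*H*W) tensor; returns (out, out_chw).

    Output layout is channels-first flat (N, Cout*OH*OW).
    """
    C, H, W = chw
    n = x.shape[0]
    xi = x.reshape(n, C, H, W).pad2d(pad).reshape(n, C * (H + 2 * pad) * (W + 2 * pad))
    index, OH, OW = _conv_index(C, H + 2 * pad, W + 2 * pad, k, k, stride)
    patches = xi.gather_patches(index)          # (N, OH*OW, C*k*k)
    out = patches.matmul(weight) + bias         # (N, OH*OW, Cout)
    cout = weight.shape[1]
    out = out.transpose_last2().reshape(n, cout * OH * OW)
    return out, (cout, OH, OW)


class ConvResNetClassifier(BaseEstimator, ClassifierMixin):
    """Tiny residual CNN over a (1, side, side) feature image.

    Stem 3x3 conv (stride 2) -> one residual block (two 3x3 convs with an
    identity skip) -> global average pooling -> linear logit.  Flat input
    rows of length side*side are reshaped internally.
    """

    def __init__(self, side=42, channels=4, n_epochs=40, lr=0.01, batch_size=64, seed=0):
        self.side = side
        self.channels = channels
        self.n_epochs = n_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed

    def _forward(self, x_flat: np.ndarray) -> Tensor:
        p = self.params_
        x = Tensor(x_flat)
        h, chw = _conv2d(x, (1, self.side, self.side), p["w0"], p["b0"], stride=2)
        h = h.relu()
        r, chw2 = _conv2d(h, chw, p["w1"], p["b1"])
        r = r.relu()
        r, _ = _conv2d(r, chw2, p["w2"], p["b2"])
        h = (h + r).relu()                       # identity skip
        n = x_flat.shape[0]
        pooled = h.reshape(n, chw[0], chw[1] * chw[2]).mean_over((2,))
        return pooled.matmul(p["w3"]) + p["b3"]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.shape[1] != self.side * self.side:
            raise ValueError(
                f"expected {self.side * self.side} flat features, got {X.shape[1]}"
            )
        rng = np.random.default_rng(self.seed)
        c = self.channels
        self.params_ = {
            "w0": parameter((9, c), rng),
            "b0": Tensor(np.zeros(c), requires_grad=True),
            "w1": parameter((9 * c, c), rng),
            "b1": Tensor(np.zeros(c), requires_grad=True),
            "w2": parameter((9 * c, c), rng, scale=0.01),
            "b2": Tensor(np.zeros(c), requires_grad=True),
            "w3": parameter((c, 1), rng),
            "b3": Tensor(np.zeros(1), requires_grad=True),
        }
        _train(self, X, y, rng)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        z = self._forward(np.asarray(X, dtype=float)).data.ravel()
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class LSTMClassifier(BaseEstimator, ClassifierMixin):
    """Single-layer LSTM over (rows, time, features); last hidden -> logit."""

    def __init__(self, hidden=8, n_epochs=60, lr=0.02, batch_size=64, seed=0):
        self.hidden = hidden
        self.n_epochs = n_epochs
        self.lr = lr
        self.batch_size = batch_size
        self.seed = seed

    def _forward(self, X3: np.ndarray) -> Tensor:
        p = self.params_
        n, T, _ = X3.shape
        H = self.hidden
        h = Tensor(np.zeros((n, H)))
        c = Tensor(np.zeros((n, H)))
        for t in range(T):
            z = Tensor(X3[:, t, :]).matmul(p["wx"]) + h.matmul(p["wh"]) + p["b"]
            i = z.slice_cols(0, H).sigmoid()
            f = z.slice_cols(H, 2 * H).sigmoid()
            g = z.slice_cols(2 * H, 3 * H).tanh()
            o = z.slice_cols(3 * H, 4 * H).sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h.matmul(p["wo"]) + p["bo"]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("LSTM input must be (rows, time, features)")
        y = np.asarray(y).astype(int)
        rng = np.random.default_rng(self.seed)
        H, F = self.hidden, X.shape[2]
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias init
        self.params_ = {
            "wx": parameter((F, 4 * H), rng),
            "wh": parameter((H, 4 * H), rng),
            "b": Tensor(b, requires_grad=True),
            "wo": parameter((H, 1), rng),
            "bo": Tensor(np.zeros(1), requires_grad=True),
        }
        _train(self, X, y, rng)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        z = self._forward(np.asarray(X, dtype=float)).data.ravel()
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _train(model, X, y, rng):
    params = [p for p in model.params_.values()]
    opt = Adam(params, lr=model.lr)
    n = X.shape[0]
    for _ in range(model.n_epochs):
        order = rng.permutation(n)
        for start in range(0, n, model.batch_size):
            idx = order[start : start + model.batch_size]
            opt.zero_grad()
            logits = model._forward(X[idx])
            loss = logits.bce_with_logits(y[idx].reshape(-1, 1))
            loss.backward()
            opt.step()
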