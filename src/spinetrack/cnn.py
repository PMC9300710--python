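"""Patch-classification network, implemented directly in numpy.

Architecture: six blocks of (3×3 convolution → batch normalization → swish
activation → 2×2 max pooling), followed by three fully connected layers
(default widths 4096, 256, n_classes) and a softmax.  Forward and backward
passes are hand-written (shifted-view convolutions, exact gradients) and
trained with Adam on a class-weighted cross-entropy; the checkpoint with the
best validation accuracy is kept.

The estimator follows the scikit-learn protocol (``fit`` / ``predict`` /
``predict_proba`` / ``get_params``), so it composes with sklearn model
selection.  Patches are standardized per-sample before entering the network,
which makes classification invariant to global intensity scaling.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ParameterError


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Conv3x3:
    """Same-padded 3×3 convolution, no bias (batch norm follows)."""

    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, 3, 3))
        self.params = ["W"]

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        out = np.zeros((n, self.W.shape[0], h, w))
        for dy in range(3):
            for dx in range(3):
                patch = xp[:, :, dy:dy + h, dx:dx + w]
                out += np.einsum("oc,nchw->nohw", self.W[:, :, dy, dx], patch,
                                 optimize=True)
        self._xp_shape = xp.shape
        self._x = x
        return out

    def backward(self, grad):
        n, co, h, w = grad.shape
        xp = np.pad(self._x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self.dW = np.zeros_like(self.W)
        dxp = np.zeros(self._xp_shape)
        for dy in range(3):
            for dx in range(3):
                patch = xp[:, :, dy:dy + h, dx:dx + w]
                self.dW[:, :, dy, dx] = np.einsum("nohw,nchw->oc", grad, patch,
                                                  optimize=True)
                dxp[:, :, dy:dy + h, dx:dx + w] += np.einsum(
                    "oc,nohw->nchw", self.W[:, :, dy, dx], grad, optimize=True)
        return dxp[:, :, 1:-1, 1:-1]


class _BatchNorm2d:
    def __init__(self, c, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps
        self.params = ["gamma", "beta"]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None, None]) / self._std[None, :, None, None]
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        n_eff = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma = (grad * self._xhat).sum(axis=(0, 2, 3))
        self.dbeta = grad.sum(axis=(0, 2, 3))
        gx = grad * self.gamma[None, :, None, None]
        mean_gx = gx.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx_xhat = (gx * self._xhat).mean(axis=(0, 2, 3), keepdims=True)
        return (gx - mean_gx - self._xhat * mean_gx_xhat) / self._std[None, :, None, None]


class _Swish:
    params: list = []

    def forward(self, x, train=True):
        self._x = x
        self._s = _sigmoid(x)
        return x * self._s

    def backward(self, grad):
        s = self._s
        return grad * (s + self._x * s * (1 - s))


class _MaxPool2:
    """2×2 stride-2 max pooling with ceil-mode (-inf) padding."""

    params: list = []

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        ph, pw = (-h) % 2, (-w) % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)),
                       constant_values=-np.inf)
        self._in_shape = (n, c, h, w)
        ho, wo = x.shape[2] // 2, x.shape[3] // 2
        xr = x.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho, wo, 4)
        self._argmax = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._in_shape
        ho, wo = grad.shape[2], grad.shape[3]
        dxr = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dxr, self._argmax[..., None], grad[..., None], axis=-1)
        dx = dxr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, 2 * ho, 2 * wo)
        return dx[:, :, :h, :w]


class _Dense:
    def __init__(self, d_in, d_out, rng):
        self.W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = ["W", "b"]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T


class _Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for i, layer in enumerate(layers):
            for name in layer.params:
                key = (i, name)
                self.m[key] = np.zeros_like(getattr(layer, name))
                self.v[key] = np.zeros_like(getattr(layer, name))

    def step(self):
        self.t += 1
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                g = getattr(layer, "d" + name)
                key = (i, name)
                self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
                self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
                mhat = self.m[key] / (1 - self.b1 ** self.t)
                vhat = self.v[key] / (1 - self.b2 ** self.t)
                p = getattr(layer, name)
                setattr(layer, name, p - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class PatchClassifier(BaseEstimator, ClassifierMixin):
    """CNN classifier over square intensity patches.

    Parameters
    ----------
    conv_channels : tuple of 6 ints
        Output channels of the six convolutional blocks.
    fc_sizes : tuple of 2 ints
        Widths of the first two fully connected layers (the third has
        ``n_classes`` units).
    class_weight : 'balanced' or None
        Weight the cross-entropy inversely to class frequency.
    val_fraction : float
        Held-out fraction used to pick the best checkpoint.
    """

    def __init__(self, conv_channels=(16, 32, 48, 64, 96, 128),
                 fc_sizes=(4096, 256), lr=1e-3, epochs=30, batch_size=32,
                 val_fraction=0.3, class_weight="balanced", seed=0):
        self.conv_channels = conv_channels
        self.fc_sizes = fc_sizes
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.class_weight = class_weight
        self.seed = seed

    @classmethod
    def small(cls, **overrides):
        """Desk-scale profile: narrower blocks, FC 4096 → 256."""
        kw = dict(conv_channels=(8, 12, 16, 16, 24, 24), fc_sizes=(256, 64),
                  epochs=25, batch_size=32)
        kw.update(overrides)
        return cls(**kw)

    # -- internal ----------------------------------------------------------

    def _build(self, side, n_classes, rng):
        if len(self.conv_channels) != 6:
            raise ParameterError("exactly six convolutional blocks are required")
        layers = []
        c_in = 1
        s = side
        for c_out in self.conv_channels:
            layers += [_Conv3x3(c_in, c_out, rng), _BatchNorm2d(c_out),
                       _Swish(), _MaxPool2()]
            c_in = c_out
            s = (s + 1) // 2
        flat = c_in * s * s
        d = flat
        for width in self.fc_sizes:
            layers += [_Dense(d, width, rng), _Swish()]
            d = width
        layers.append(_Dense(d, n_classes, rng))
        self._flat_dim = flat
        return layers

    def _forward(self, x, train):
        out = x
        flatten_at = None
        for i, layer in enumerate(self.layers_):
            if isinstance(layer, _Dense) and out.ndim == 4:
                flatten_at = i
                out = out.reshape(out.shape[0], -1)
            out = layer.forward(out, train=train)
        self._flatten_at = flatten_at
        return out

    def _backward(self, grad, conv_out_shape):
        for i in range(len(self.layers_) - 1, -1, -1):
            grad = self.layers_[i].backward(grad)
            if i == self._flatten_at:
                grad = grad.reshape(conv_out_shape)
        return grad

    @staticmethod
    def _standardize(X):
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=(1, 2), keepdims=True)
        std = X.std(axis=(1, 2), keepdims=True)
        std[std == 0] = 1.0
        return (X - mean) / std

    # -- sklearn interface -------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ParameterError("X must be (n, side, side)")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ParameterError("training needs at least two classes")
        if not (0 < self.val_fraction < 1):
            raise ParameterError("val_fraction must be in (0, 1)")
        rng = np.random.default_rng(self.seed)
        self.input_side_ = X.shape[1]
        n_classes = len(self.classes_)
        y_idx = np.searchsorted(self.classes_, y)

        Xs = self._standardize(X)[:, None, :, :]  # (n, 1, s, s)
        perm = rng.permutation(len(Xs))
        n_val = max(int(round(self.val_fraction * len(Xs))), 1)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if len(train_idx) == 0:
            raise ParameterError("not enough samples for the requested split")

        if self.class_weight == "balanced":
            counts = np.bincount(y_idx, minlength=n_classes).astype(float)
            counts[counts == 0] = 1.0
            weights = len(y_idx) / (n_classes * counts)
        else:
            weights = np.ones(n_classes)

        self.layers_ = self._build(self.input_side_, n_classes, rng)
        opt = _Adam(self.layers_, lr=self.lr)
        best_acc, best_state = -1.0, None
        self.history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(train_idx)
            for start in range(0, len(order), self.batch_size):
                batch = order[start:start + self.batch_size]
                xb, yb = Xs[batch], y_idx[batch]
                logits = self._forward(xb, train=True)
                probs = _softmax(logits)
                wb = weights[yb]
                grad = probs.copy()
                grad[np.arange(len(yb)), yb] -= 1.0
                grad *= wb[:, None] / wb.sum()
                conv_shape = (len(batch), self.conv_channels[-1],
                              *self._conv_out_side())
                self._backward(grad, conv_shape)
                opt.step()
            acc = self._accuracy(Xs[val_idx], y_idx[val_idx])
            self.history_.append(acc)
            if acc > best_acc:
                best_acc = acc
                best_state = copy.deepcopy(
                    [{p: getattr(l, p).copy() for p in l.params}
                     | ({"running_mean": l.running_mean.copy(),
                         "running_var": l.running_var.copy()}
                        if isinstance(l, _BatchNorm2d) else {})
                     for l in self.layers_])
        for layer, state in zip(self.layers_, best_state):
            for k, v in state.items():
                setattr(layer, k, v)
        self.best_val_accuracy_ = best_acc
        self._val_idx = val_idx
        self._train_idx = train_idx
        return self

    def _conv_out_side(self):
        s = self.input_side_
        for _ in range(6):
            s = (s + 1) // 2
        return (s, s)

    def _accuracy(self, Xs, y_idx):
        pred = []
        for start in range(0, len(Xs), 256):
            logits = self._forward(Xs[start:start + 256], train=False)
            pred.append(logits.argmax(axis=1))
        return float((np.concatenate(pred) == y_idx).mean()) if len(Xs) else 0.0

    def predict_proba(self, X):
        if not hasattr(self, "layers_"):
            raise ParameterError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.input_side_:
            from skimage.transform import resize
            X = np.stack([resize(p, (self.input_side_, self.input_side_),
                                 preserve_range=True) for p in X])
        Xs = self._standardize(X)[:, None, :, :]
        out = []
        for start in range(0, len(Xs), 256):
            logits = self._forward(Xs[start:start + 256], train=False)
            out.append(_softmax(logits))
        return np.vstack(out) if out else np.empty((0, len(self.classes_)))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
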