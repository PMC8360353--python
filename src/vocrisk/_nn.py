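"""Minimal numpy neural-network core.

Implements exactly the pieces the pipeline's two neural models need —
1-D convolution (im2col), max pooling, global average pooling, dense
layers, ReLU, dropout — trained with Adam on a class-weighted binary
cross-entropy, with early stopping on a stratified validation split.
Everything is seed-deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv1d", "MaxPool1d", "GlobalAvgPool1d", "ReLU", "Dropout",
           "Flatten", "Network", "Trainer"]


class Layer:
    def params(self):  # (param, grad) pairs
        return []

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Conv1d(Layer):
    """'Same'-padded 1-D convolution, stride 1, via im2col."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.k = kernel
        self.c_in = c_in
        self.c_out = c_out
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, (c_out, c_in * kernel))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, x):
        n, c, length = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        s = xp.strides
        cols = np.lib.stride_tricks.as_strided(
            xp, shape=(n, c, length, self.k), strides=(s[0], s[1], s[2], s[2])
        )
        # (n, L, c*k)
        return cols.transpose(0, 2, 1, 3).reshape(n, length, c * self.k)

    def forward(self, x, train=False):
        self._shape = x.shape
        self._cols = self._im2col(x)
        y = self._cols @ self.W.T + self.b  # (n, L, c_out)
        return y.transpose(0, 2, 1)

    def backward(self, grad):
        n, _, length = self._shape
        g = grad.transpose(0, 2, 1)  # (n, L, c_out)
        self.dW[...] = g.reshape(-1, self.c_out).T @ self._cols.reshape(-1, self.c_in * self.k)
        self.db[...] = g.sum(axis=(0, 1))
        dcols = g @ self.W  # (n, L, c_in*k)
        dcols = dcols.reshape(n, length, self.c_in, self.k)
        p = self.k // 2
        dx = np.zeros((n, self.c_in, length + 2 * p))
        for j in range(self.k):
            dx[:, :, j : j + length] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dx[:, :, p : p + length]


class MaxPool1d(Layer):
    def __init__(self, pool: int):
        self.p = pool

    def forward(self, x, train=False):
        n, c, length = x.shape
        l_out = length // self.p
        xr = x[:, :, : l_out * self.p].reshape(n, c, l_out, self.p)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad):
        n, c, l_out = grad.shape
        dx = np.zeros(self._shape)
        dxr = dx[:, :, : l_out * self.p].reshape(n, c, l_out, self.p)
        idx = np.ogrid[:n, :c, :l_out]
        dxr[idx[0], idx[1], idx[2], self._arg] = grad
        return dx


class GlobalAvgPool1d(Layer):
    def forward(self, x, train=False):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class ReLU(Layer):
    def forward(self, x, train=False):
        self._m = x > 0
        return x * self._m

    def backward(self, grad):
        return grad * self._m


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Network:
    """A plain layer stack ending in a single logit."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x.ravel()

    def backward(self, grad):
        g = grad[:, None]
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def predict_proba(self, x, batch: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch):
            z = self.forward(x[i : i + batch], train=False)
            out.append(1.0 / (1.0 + np.exp(-z)))
        return np.concatenate(out) if out else np.empty(0)

    def get_weights(self):
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights):
        for (p, _), w in zip(self.params(), weights):
            p[...] = w


def _bce_with_logits(z, y, w):
    """Class-weighted binary cross-entropy; returns (mean loss, dloss/dz)."""
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    sig = 1.0 / (1.0 + np.exp(-z))
    n = len(z)
    return float((w * loss).sum() / n), w * (sig - y) / n


class Trainer:
    """Adam + early stopping on a stratified 20% validation split."""

    def __init__(
        self,
        net: Network,
        lr: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 100,
        patience: int = 5,
        val_fraction: float = 0.2,
        min_epochs: int = 20,
        seed: int = 0,
    ):
        self.net = net
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        # patience only starts counting after min_epochs: tiny validation
        # splits are noisy early on and would otherwise freeze garbage weights
        self.min_epochs = min(min_epochs, max_epochs)
        self.rng = np.random.default_rng(seed)
        self.history: list[float] = []

    def _split(self, y):
        idx = np.arange(len(y))
        val = []
        for cls in (0, 1):
            c = idx[y == cls]
            c = c[self.rng.permutation(len(c))]
            n_val = max(1, int(round(self.val_fraction * len(c)))) if len(c) > 1 else 0
            val.extend(c[:n_val])
        val = np.array(sorted(val), dtype=int)
        train = np.setdiff1d(idx, val)
        return train, val

    def fit(self, x: np.ndarray, y: np.ndarray, class_weight: dict[int, float]):
        y = np.asarray(y, dtype=float)
        w_all = np.where(y == 1, class_weight.get(1, 1.0), class_weight.get(0, 1.0))
        tr, va = self._split(y.astype(int))
        if len(va) == 0 or self.patience <= 0:
            tr = np.arange(len(y))
            va = np.empty(0, dtype=int)

        params = self.net.params()
        m = [np.zeros_like(p) for p, _ in params]
        v = [np.zeros_like(p) for p, _ in params]
        t = 0
        best_val = np.inf
        best_weights = self.net.get_weights()
        stale = 0
        for epoch in range(self.max_epochs):
            order = self.rng.permutation(tr)
            epoch_loss = 0.0
            for i in range(0, len(order), self.batch_size):
                batch = order[i : i + self.batch_size]
                z = self.net.forward(x[batch], train=True)
                loss, dz = _bce_with_logits(z, y[batch], w_all[batch])
                epoch_loss += loss * len(batch)
                self.net.backward(dz)
                t += 1
                for j, (p, g) in enumerate(params):
                    m[j] = 0.9 * m[j] + 0.1 * g
                    v[j] = 0.999 * v[j] + 0.001 * g * g
                    mh = m[j] / (1 - 0.9**t)
                    vh = v[j] / (1 - 0.999**t)
                    p -= self.lr * mh / (np.sqrt(vh) + 1e-8)
            self.history.append(epoch_loss / max(len(order), 1))
            if len(va):
                zv = self.net.forward(x[va], train=False)
                val_loss, _ = _bce_with_logits(zv, y[va], w_all[va])
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_weights = self.net.get_weights()
                    stale = 0
                else:
                    stale += 1
                    if epoch + 1 >= self.min_epochs and stale >= self.patience:
                        break
        if len(va):
            self.net.set_weights(best_weights)
        return self
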