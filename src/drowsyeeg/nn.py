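"""Minimal numpy neural-network core used by the CNN models.

Implements exactly the pieces the drowsiness models need -- 2-D/1-D
convolution ('same' padding), ReLU, max pooling, inverted dropout,
dense layers, Adam, and binary cross-entropy on logits -- with a plain
training loop (mini-batches, stratified validation split, early
stopping with best-weight restore).  Everything is float32 and fully
deterministic given a seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np


class Layer:
    """Base layer; stateless layers override forward/backward only."""

    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3-style convolution, stride 1, 'same' zero padding, NHWC layout."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        super().__init__()
        kh, kw = kernel
        fan_in = kh * kw * in_ch
        w = rng.standard_normal((kh, kw, in_ch, out_ch)) * np.sqrt(2.0 / fan_in)
        self.params = {"w": w.astype(np.float32), "b": np.zeros(out_ch, np.float32)}
        self.kernel = kernel

    def forward(self, x, training, rng):
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        self._xp = xp
        n, h, w_, _ = x.shape
        out = np.broadcast_to(self.params["b"], (n, h, w_, self.params["b"].size)).copy()
        W = self.params["w"]
        for di in range(kh):
            for dj in range(kw):
                out += xp[:, di:di + h, dj:dj + w_, :] @ W[di, dj]
        return out

    def backward(self, grad):
        kh, kw = self.kernel
        ph, pw = kh // 2, kw // 2
        xp = self._xp
        n, hp, wp, cin = xp.shape
        h, w_ = hp - 2 * ph, wp - 2 * pw
        W = self.params["w"]
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        g2 = grad.reshape(-1, grad.shape[-1])
        for di in range(kh):
            for dj in range(kw):
                patch = xp[:, di:di + h, dj:dj + w_, :].reshape(-1, cin)
                dW[di, dj] = patch.T @ g2
                dxp[:, di:di + h, dj:dj + w_, :] += grad @ W[di, dj].T
        self.grads = {"w": dW, "b": grad.sum(axis=(0, 1, 2))}
        return dxp[:, ph:ph + h, pw:pw + w_, :]


class Conv1D(Layer):
    """1-D convolution with configurable stride, 'same'-style padding, NLC layout."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        fan_in = kernel * in_ch
        w = rng.standard_normal((kernel, in_ch, out_ch)) * np.sqrt(2.0 / fan_in)
        self.params = {"w": w.astype(np.float32), "b": np.zeros(out_ch, np.float32)}
        self.kernel = kernel
        self.stride = stride

    def _cols(self, xp: np.ndarray, l_out: int) -> np.ndarray:
        n, _, cin = xp.shape
        s0, s1, s2 = xp.strides
        return np.lib.stride_tricks.as_strided(
            xp, (n, l_out, self.kernel, cin), (s0, self.stride * s1, s1, s2)
        )

    def forward(self, x, training, rng):
        n, l, cin = x.shape
        k, s = self.kernel, self.stride
        l_out = int(np.ceil(l / s))
        pad_total = max((l_out - 1) * s + k - l, 0)
        pl, pr = pad_total // 2, pad_total - pad_total // 2
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        self._xp, self._pl, self._l = xp, pl, l
        cols = self._cols(xp, l_out).reshape(n * l_out, k * cin)
        self._cols_mat = cols
        W = self.params["w"].reshape(k * cin, -1)
        out = cols @ W + self.params["b"]
        return out.reshape(n, l_out, -1)

    def backward(self, grad):
        n, l_out, cout = grad.shape
        k, s = self.kernel, self.stride
        cin = self._xp.shape[2]
        g2 = grad.reshape(n * l_out, cout)
        dW = (self._cols_mat.T @ g2).reshape(k, cin, cout)
        self.grads = {"w": dW, "b": g2.sum(axis=0)}
        dcols = (g2 @ self.params["w"].reshape(k * cin, cout).T).reshape(n, l_out, k, cin)
        dxp = np.zeros_like(self._xp)
        for t in range(k):
            idx = np.arange(l_out) * s + t
            np.add.at(dxp, (slice(None), idx, slice(None)), dcols[:, :, t, :])
        return dxp[:, self._pl:self._pl + self._l, :]


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 valid max pooling (odd trailing rows/columns cropped)."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training, rng):
        p = self.pool
        n, h, w, c = x.shape
        h2, w2 = h // p, w // p
        self._in_shape = x.shape
        xc = x[:, :h2 * p, :w2 * p, :].reshape(n, h2, p, w2, p, c)
        xc = xc.transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, p * p)
        self._arg = xc.argmax(axis=-1)
        return np.take_along_axis(xc, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        p = self.pool
        n, h, w, c = self._in_shape
        h2, w2 = h // p, w // p
        dxc = np.zeros((n, h2, w2, c, p * p), grad.dtype)
        np.put_along_axis(dxc, self._arg[..., None], grad[..., None], axis=-1)
        dxc = dxc.reshape(n, h2, w2, c, p, p).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._in_shape, grad.dtype)
        dx[:, :h2 * p, :w2 * p, :] = dxc.reshape(n, h2 * p, w2 * p, c)
        return dx


class MaxPool1D(Layer):
    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x, training, rng):
        p = self.pool
        n, l, c = x.shape
        l2 = l // p
        self._in_shape = x.shape
        xc = x[:, :l2 * p, :].reshape(n, l2, p, c).transpose(0, 1, 3, 2)
        self._arg = xc.argmax(axis=-1)
        return np.take_along_axis(xc, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        p = self.pool
        n, l, c = self._in_shape
        l2 = l // p
        dxc = np.zeros((n, l2, c, p), grad.dtype)
        np.put_along_axis(dxc, self._arg[..., None], grad[..., None], axis=-1)
        dx = np.zeros(self._in_shape, grad.dtype)
        dx[:, :l2 * p, :] = dxc.transpose(0, 1, 3, 2).reshape(n, l2 * p, c)
        return dx


class Dropout(Layer):
    def __init__(self, rate: float):
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.params = {"w": w.astype(np.float32), "b": np.zeros(n_out, np.float32)}

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad):
        self.grads = {"w": self._x.T @ grad, "b": grad.sum(axis=0)}
        return grad @ self.params["w"].T


class Sequential:
    """A feed-forward stack of layers with a designated feature tap."""

    def __init__(self, layers: list[Layer], feature_index: int | None = None):
        self.layers = layers
        #: index such that layers[:feature_index] maps input -> features
        self.feature_index = feature_index

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None,
                until: int | None = None) -> np.ndarray:
        out = np.asarray(x, np.float32)
        for layer in self.layers[:until]:
            out = layer.forward(out, training, rng)
        return out

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def features(self, x: np.ndarray) -> np.ndarray:
        if self.feature_index is None:
            raise ValueError("network has no feature tap")
        return self.forward(x, training=False, until=self.feature_index)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def n_params(self) -> int:
        return sum(layer.params[n].size for layer, n in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"{i}.{name}": layer.params[name]
            for i, layer in enumerate(self.layers) for name in layer.params
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = np.asarray(state[f"{i}.{name}"], np.float32)


class Adam:
    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in net.state_dict().items()}
        self.v = {k: np.zeros_like(v) for k, v in net.state_dict().items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, layer in enumerate(self.net.layers):
            for name, g in layer.grads.items():
                key = f"{i}.{name}"
                self.m[key] = b1 * self.m[key] + (1 - b1) * g
                self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
                mh = self.m[key] / (1 - b1**self.t)
                vh = self.v[key] / (1 - b2**self.t)
                layer.params[name] -= self.lr * mh / (np.sqrt(vh) + self.eps)


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits and its gradient."""
    z = logits.ravel()
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    p = 1.0 / (1.0 + np.exp(-z))
    grad = ((p - y) / z.size).astype(np.float32).reshape(logits.shape)
    return loss, grad


def _stratified_split(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Indices of a stratified holdout of about ``fraction`` of the data."""
    val_idx = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = max(1, int(round(fraction * idx.size)))
        val_idx.append(idx[:k])
    val = np.concatenate(val_idx)
    mask = np.ones(y.size, bool)
    mask[val] = False
    return np.flatnonzero(mask), val


@dataclass
class History:
    """Per-epoch training curves."""

    loss: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


def train(
    net: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 50,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    patience: int = 10,
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> History:
    """Train a binary-output network with Adam, BCE and early stopping.

    A stratified ``validation_fraction`` of the data monitors the loss;
    training stops once it has not improved for ``patience`` epochs and
    the best weights are restored.
    """
    X = np.asarray(X, np.float32)
    y = np.asarray(y, np.float32).ravel()
    if np.unique(y).size < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(seed)
    tr_idx, val_idx = _stratified_split(y, validation_fraction, rng)
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    opt = Adam(net, lr=learning_rate)
    hist = History()
    best_loss, best_state, since_best = np.inf, None, 0
    for _ in range(epochs):
        order = rng.permutation(len(Xtr))
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, len(order), batch_size):
            sl = order[start:start + batch_size]
            logits = net.forward(Xtr[sl], training=True, rng=rng)
            loss, grad = bce_with_logits(logits, ytr[sl])
            net.backward(grad)
            opt.step()
            ep_loss += loss * sl.size
            ep_correct += int(np.sum((logits.ravel() > 0) == ytr[sl]))
        val_logits = net.forward(Xval, training=False)
        val_loss, _ = bce_with_logits(val_logits, yval)
        hist.loss.append(ep_loss / len(Xtr))
        hist.accuracy.append(ep_correct / len(Xtr))
        hist.val_loss.append(val_loss)
        hist.val_accuracy.append(float(np.mean((val_logits.ravel() > 0) == yval)))
        if val_loss < best_loss - 1e-5:
            best_loss, since_best = val_loss, 0
            best_state = copy.deepcopy(net.state_dict())
        else:
            since_best += 1
            if since_best >= patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    return hist
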