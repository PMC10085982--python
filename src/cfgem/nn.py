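"""Compact numpy neural-net engine.

Implements exactly the pieces the detection/localization models need —
dense and 3x3 same-padding convolution layers, batch normalization,
ReLU, inverted dropout, sigmoid/softmax heads with class-weighted
cross-entropy, the AdamW optimizer, and early-stopped minibatch
training — with analytic backpropagation all the way to the *input*,
which is what integrated-gradients attribution differentiates.

All shapes are channels-last: dense inputs are (N, F), image inputs
are (N, H, W, C).  Every random draw (init, shuffling, dropout) comes
from a generator passed in by the caller, so training is bit
reproducible for a fixed seed on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cfgem.errors import InvalidInputError

DTYPE = np.float32


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]
    decay: list[bool]  # apply weight decay to the matching param?

    def __init__(self):
        self.params, self.grads, self.decay = [], [], []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(DTYPE)
        b = np.zeros(n_out, dtype=DTYPE)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.decay = [True, False]

    def forward(self, x, train):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, dy, need_dx=True):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.params[0].T if need_dx else None


class Conv3x3(Layer):
    """3x3 stride-1 same-padding convolution on NHWC arrays.

    Implemented as nine shifted matrix products over the channel axis,
    which keeps memory bounded and leans on BLAS.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / (9 * c_in)), size=(3, 3, c_in, c_out)).astype(DTYPE)
        b = np.zeros(c_out, dtype=DTYPE)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]
        self.decay = [True, False]

    def forward(self, x, train):
        n, h, w_, c = x.shape
        xp = np.zeros((n, h + 2, w_ + 2, c), dtype=DTYPE)
        xp[:, 1:-1, 1:-1, :] = x
        self._xp = xp
        w = self.params[0]
        out = np.empty((n, h, w_, w.shape[3]), dtype=DTYPE)
        out[...] = self.params[1]
        for i in range(3):
            for j in range(3):
                out += xp[:, i:i + h, j:j + w_, :] @ w[i, j]
        return out

    def backward(self, dy, need_dx=True):
        n, h, w_, c_out = dy.shape
        w = self.params[0]
        dyr = dy.reshape(-1, c_out)
        self.grads[1][...] = dyr.sum(axis=0)
        dxp = np.zeros(self._xp.shape, dtype=DTYPE) if need_dx else None
        for i in range(3):
            for j in range(3):
                patch = np.ascontiguousarray(self._xp[:, i:i + h, j:j + w_, :]).reshape(-1, self._xp.shape[-1])
                self.grads[0][i, j] = patch.T @ dyr
                if need_dx:
                    dxp[:, i:i + h, j:j + w_, :] += dy @ w[i, j].T
        if not need_dx:
            return None
        return dxp[:, 1:-1, 1:-1, :]


class BatchNorm(Layer):
    """Normalize over all axes but the last; running stats for eval."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(n_features, dtype=DTYPE)
        self.beta = np.zeros(n_features, dtype=DTYPE)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.decay = [False, False]
        self.run_mean = np.zeros(n_features, dtype=DTYPE)
        self.run_var = np.ones(n_features, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean[...] = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var[...] = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._inv = (1.0 / np.sqrt(var + self.eps)).astype(DTYPE, copy=False)
        self._xhat = (x - mean) * self._inv
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._train = train
        return self.params[0] * self._xhat + self.params[1]

    def backward(self, dy, need_dx=True):
        self.grads[0][...] = (dy * self._xhat).sum(axis=self._axes)
        self.grads[1][...] = dy.sum(axis=self._axes)
        if not need_dx:
            return None
        g = self.params[0]
        if not self._train:  # eval mode: affine map with fixed stats
            return dy * g * self._inv
        m = self._m
        dxhat = dy * g
        return (self._inv / m) * (m * dxhat - dxhat.sum(axis=self._axes)
                                  - self._xhat * (dxhat * self._xhat).sum(axis=self._axes))


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy, need_dx=True):
        return dy * self._mask if need_dx else None


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = float(rate), rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u >= self.rate).astype(DTYPE) / DTYPE(1.0 - self.rate)
        return x * self._mask

    def backward(self, dy, need_dx=True):
        if not need_dx:
            return None
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy, need_dx=True):
        return dy.reshape(self._shape) if need_dx else None


# ---------------------------------------------------------------------------
# network + loss heads
# ---------------------------------------------------------------------------

@dataclass
class Network:
    """A feed-forward stack ending in a sigmoid or softmax head.

    ``task`` is ``"detection"`` (single sigmoid output) or
    ``"localization"`` (softmax over classes).  ``class_weights`` enter
    the cross-entropy loss per sample; with balanced classes and unit
    weights the loss reduces to the unweighted one.
    """

    layers: list[Layer]
    task: str
    n_classes: int = 1
    class_weights: np.ndarray | None = None

    def forward_logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = x.astype(DTYPE)
        for lyr in self.layers:
            h = lyr.forward(h, train)
        return h

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.forward_logits(x, train=False)
        if self.task == "detection":
            return _sigmoid(z[:, 0].astype(np.float64))
        return _softmax(z.astype(np.float64))

    def loss(self, x: np.ndarray, y: np.ndarray, train: bool) -> tuple[float, np.ndarray]:
        """Class-weighted cross-entropy; returns (loss, dlogits)."""
        z = self.forward_logits(x, train)
        n = len(y)
        if self.task == "detection":
            p = _sigmoid(z[:, 0].astype(np.float64))
            w = np.ones(n) if self.class_weights is None else self.class_weights[y.astype(int)]
            eps = 1e-12
            loss = -np.mean(w * (y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
            dz = (w * (p - y) / n)[:, None].astype(DTYPE)
        else:
            p = _softmax(z.astype(np.float64))
            w = np.ones(n) if self.class_weights is None else self.class_weights[y.astype(int)]
            eps = 1e-12
            loss = -np.mean(w * np.log(p[np.arange(n), y.astype(int)] + eps))
            grad = p.copy()
            grad[np.arange(n), y.astype(int)] -= 1.0
            dz = (grad * (w / n)[:, None]).astype(DTYPE)
        return float(loss), dz

    def backward(self, dz: np.ndarray) -> None:
        dy = dz
        for i in range(len(self.layers) - 1, -1, -1):
            dy = self.layers[i].backward(dy, need_dx=(i > 0))

    def input_gradient(self, x: np.ndarray, class_idx: int | None = None) -> np.ndarray:
        """d(score)/d(input) in eval mode, per sample.

        The score is the sigmoid output for detection, or the softmax
        probability of ``class_idx`` for localization.
        """
        z = self.forward_logits(x, train=False)
        if self.task == "detection":
            s = _sigmoid(z[:, 0].astype(np.float64))
            dz = (s * (1 - s))[:, None]
        else:
            if class_idx is None:
                raise InvalidInputError("class_idx required for localization gradients")
            p = _softmax(z.astype(np.float64))
            dz = -p * p[:, [class_idx]]
            dz[:, class_idx] += p[:, class_idx]
        dy = dz.astype(DTYPE)
        for i in range(len(self.layers) - 1, -1, -1):
            dy = self.layers[i].backward(dy, need_dx=True)
        return dy.astype(np.float64)

    # -- parameter plumbing ------------------------------------------------
    def parameters(self):
        for lyr in self.layers:
            yield from zip(lyr.params, lyr.grads, lyr.decay)

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for lyr in self.layers for p in lyr.params]
        state += [lyr.run_mean.copy() for lyr in self.layers if isinstance(lyr, BatchNorm)]
        state += [lyr.run_var.copy() for lyr in self.layers if isinstance(lyr, BatchNorm)]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for lyr in self.layers:
            for p in lyr.params:
                p[...] = next(it)
        for lyr in self.layers:
            if isinstance(lyr, BatchNorm):
                lyr.run_mean[...] = next(it)
        for lyr in self.layers:
            if isinstance(lyr, BatchNorm):
                lyr.run_var[...] = next(it)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def class_weight_map(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Balanced class weights: n / (k * n_c)."""
    counts = np.bincount(y.astype(int), minlength=n_classes).astype(float)
    counts[counts == 0] = 1.0
    return len(y) / (n_classes * counts)


def init_output_bias(net: Network, y: np.ndarray) -> None:
    """Initialize the output layer bias to log prior odds (log priors)."""
    last = [l for l in net.layers if isinstance(l, Dense)][-1]
    if net.task == "detection":
        p = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        last.params[1][...] = np.log(p / (1 - p))
    else:
        pri = np.bincount(y.astype(int), minlength=net.n_classes).astype(float)
        pri = np.clip(pri / pri.sum(), 1e-6, None)
        last.params[1][...] = np.log(pri)


# ---------------------------------------------------------------------------
# optimizer + training loop
# ---------------------------------------------------------------------------

class AdamW:
    def __init__(self, net: Network, lr: float = 1e-3, weight_decay: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.net, self.lr, self.wd = net, lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _, _ in net.parameters()]
        self.v = [np.zeros_like(p) for p, _, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, (p, g, decay) in enumerate(self.net.parameters()):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            upd = (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            if decay and self.wd:
                upd = upd + self.wd * p
            p -= (self.lr * upd).astype(p.dtype)


@dataclass
class TrainResult:
    val_loss: float
    n_epochs: int
    history: list[tuple[float, float]] = field(default_factory=list)


def train_network(
    net: Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
    lr: float = 1e-3,
    weight_decay: float = 1e-4,
    batch_size: int = 32,
    max_epochs: int = 200,
    patience: int = 50,
) -> TrainResult:
    """Minibatch AdamW training with early stopping on validation loss.

    The best-validation parameter state is restored before returning.
    """
    if len(x_val) == 0:
        raise InvalidInputError("empty validation set")
    opt = AdamW(net, lr=lr, weight_decay=weight_decay)
    best = np.inf
    best_state = net.get_state()
    since = 0
    history = []
    n = len(x_train)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        tr_loss = 0.0
        for i0 in range(0, n, batch_size):
            idx = order[i0:i0 + batch_size]
            loss, dz = net.loss(x_train[idx], y_train[idx], train=True)
            net.backward(dz)
            opt.step()
            tr_loss += loss * len(idx)
        val_loss, _ = net.loss(x_val, y_val, train=False)
        history.append((tr_loss / n, val_loss))
        if val_loss < best - 1e-9:
            best, best_state, since = val_loss, net.get_state(), 0
        else:
            since += 1
            if since > patience:
                break
    net.set_state(best_state)
    return TrainResult(val_loss=float(best), n_epochs=len(history), history=history)
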