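"""CNN classifier for gene-expression vectors, implemented in NumPy.

The gene vector is reshaped row-major onto the smallest square grid (zero
padded) and pushed through six convolutional blocks with 8, 16, 32, 64, 128
and 256 filters of size 2x2, stride 1. Each block is conv -> batch-norm ->
ReLU -> 2x2/stride-2 max-pool, except the last block which omits the pool;
pooling is also skipped once a spatial dimension drops below 2. A flatten ->
dense -> softmax head produces class probabilities.

Convolutions preserve the spatial size (one-pixel zero pad on the bottom and
right edges of the 2x2 kernel); on the small grids gene vectors produce,
shrinking ("valid") convolutions would leave the deeper blocks with nothing
to convolve. Training is mini-batch Adam on the cross-entropy loss, with
forward and backward passes written directly in NumPy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets_io import ExpressionDataset
from .errors import ConfigError, ValidationError
from .fitness import FitnessResult

_EPS = 1e-5


@dataclass(frozen=True)
class CNNArchitecture:
    conv_channels: tuple[int, ...] = (8, 16, 32, 64, 128, 256)
    kernel: int = 2
    stride: int = 1

    def __post_init__(self) -> None:
        if self.kernel != 2 or self.stride != 1:
            raise ConfigError("architecture is fixed at 2x2 kernels, stride 1")


@dataclass(frozen=True)
class TrainConfig:
    """Training defaults: Adam(1e-3) with decoupled weight decay 1e-4,
    cross-entropy, batch min(16, N_train), stratified 80/20 split, 100
    epochs. Batch-norm statistics are recalibrated over the full training
    set after the last epoch (small batches leave the running averages
    noisy otherwise)."""

    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int | None = None
    test_fraction: float = 0.2
    weight_decay: float = 1e-4
    seed: int = 0


def reshape_to_grid(vec: np.ndarray) -> np.ndarray:
    """Row-major fill of the smallest square grid, zero-padded."""
    vec = np.asarray(vec, dtype=float).ravel()
    if vec.size < 1:
        raise ValidationError("need at least one feature")
    side = int(np.ceil(np.sqrt(vec.size)))
    grid = np.zeros(side * side)
    grid[: vec.size] = vec
    return grid.reshape(side, side)


class _Param:
    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class _Conv2x2:
    """2x2 convolution, stride 1, size-preserving (pad bottom/right)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 4))
        self.w = _Param(rng.normal(0.0, scale, size=(c_out, c_in, 2, 2)))
        self.b = _Param(np.zeros(c_out))
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.zeros((n, c, h + 1, w + 1))
        xp[:, :, :h, :w] = x
        self._xp, self._hw = xp, (h, w)
        out = np.tile(self.b.value.reshape(1, -1, 1, 1), (n, 1, h, w)).astype(float)
        for di in (0, 1):
            for dj in (0, 1):
                out += np.einsum(
                    "oc,nchw->nohw",
                    self.w.value[:, :, di, dj],
                    xp[:, :, di : di + h, dj : dj + w],
                )
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        xp = self._xp
        dxp = np.zeros_like(xp)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        for di in (0, 1):
            for dj in (0, 1):
                self.w.grad[:, :, di, dj] += np.einsum(
                    "nohw,nchw->oc", dy, xp[:, :, di : di + h, dj : dj + w]
                )
                dxp[:, :, di : di + h, dj : dj + w] += np.einsum(
                    "oc,nohw->nchw", self.w.value[:, :, di, dj], dy
                )
        return dxp[:, :, :h, :w]


class _BatchNorm:
    """Per-channel batch normalization with running statistics (momentum 0.1)."""

    def __init__(self, channels: int):
        self.gamma = _Param(np.ones(channels))
        self.beta = _Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.params = [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = 0.9 * self.running_mean + 0.1 * mean
            self.running_var = 0.9 * self.running_var + 0.1 * var
        else:
            mean, var = self.running_mean, self.running_var
        m = mean.reshape(1, -1, 1, 1)
        s = np.sqrt(var + _EPS).reshape(1, -1, 1, 1)
        xhat = (x - m) / s
        self._xhat, self._s, self._n = xhat, s, x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma.value.reshape(1, -1, 1, 1) * xhat + self.beta.value.reshape(
            1, -1, 1, 1
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, s, n = self._xhat, self._s, self._n
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value.reshape(1, -1, 1, 1)
        dxhat = dy * g
        sum_d = dxhat.sum(axis=(0, 2, 3), keepdims=True).reshape(1, -1, 1, 1)
        sum_dx = (dxhat * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        return (dxhat - sum_d / n - xhat * sum_dx / n) / s


class _ReLU:
    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool:
    """2x2 max pool, stride 2, ceil mode (odd sides padded with -inf so no
    cell is discarded -- on the small gene grids a dropped trailing row can
    hold planted genes)."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            xp = np.full((n, c, h + ph, w + pw), -np.inf)
            xp[:, :, :h, :w] = x
        else:
            xp = x
        h2, w2 = xp.shape[2] // 2, xp.shape[3] // 2
        t = xp.reshape(n, c, h2, 2, w2, 2)
        t = t.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._argmax = t.argmax(axis=-1)
        self._pad = (ph, pw)
        return t.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        ph, pw = self._pad
        h2, w2 = (h + ph) // 2, (w + pw) // 2
        dt = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dt, self._argmax[..., None], dy[..., None], axis=-1)
        dt = dt.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = dt.reshape(n, c, h + ph, w + pw)
        return dx[:, :, :h, :w]


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = _Param(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)))
        self.b = _Param(np.zeros(d_out))
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNModel:
    """The six-block convolutional classifier with an Adam training loop."""

    def __init__(self, d: int, n_classes: int, arch: CNNArchitecture, seed: int = 0):
        if d < 1 or n_classes < 2:
            raise ConfigError("need d >= 1 and n_classes >= 2")
        rng = np.random.default_rng(seed)
        self.d = d
        self.n_classes = n_classes
        self.arch = arch
        side = max(int(np.ceil(np.sqrt(d))), 2)  # 2x2 minimum input grid
        self.side = side
        self.layers: list = []
        self.shape_report: list[dict] = []
        c_in = 1
        n_blocks = len(arch.conv_channels)
        for bi, c_out in enumerate(arch.conv_channels):
            conv = _Conv2x2(c_in, c_out, rng)
            self.layers += [conv, _BatchNorm(c_out), _ReLU()]
            pooled = bi < n_blocks - 1 and side >= 2
            if pooled:
                self.layers.append(_MaxPool())
                side = (side + 1) // 2  # ceil-mode pool
            n_params = conv.w.value.size + conv.b.value.size
            self.shape_report.append(
                {
                    "block": bi + 1,
                    "out_channels": c_out,
                    "spatial": side,
                    "pooled": pooled,
                    "conv_params": n_params,
                }
            )
            c_in = c_out
            side = max(side, 1)
        self.flat_dim = c_in * side * side
        self.head = _Dense(self.flat_dim, n_classes, rng)
        self._t = 0  # Adam step counter

    @property
    def params(self) -> list[_Param]:
        out = []
        for layer in self.layers:
            out += layer.params
        return out + self.head.params

    def _grids(self, x: np.ndarray) -> np.ndarray:
        grids = np.stack([reshape_to_grid(row) for row in np.atleast_2d(x)])
        if grids.shape[1] < 2:  # 1x1 grid: pad up to the 2x2 minimum
            padded = np.zeros((grids.shape[0], 2, 2))
            padded[:, :1, :1] = grids
            grids = padded
        return grids[:, None, :, :]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self._grids(x)
        for layer in self.layers:
            h = layer.forward(h, train)
        self._pre_flat_shape = h.shape
        logits = self.head.forward(h.reshape(h.shape[0], -1), train)
        return logits

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return _softmax(self.forward(x, train=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    def _backward(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits).reshape(self._pre_flat_shape)
        for layer in reversed(self.layers):
            dh = layer.backward(dh)

    def recalibrate_batchnorm(self, x: np.ndarray) -> None:
        """Set batch-norm running statistics from one pass over ``x``."""
        h = self._grids(x)
        for layer in self.layers:
            if isinstance(layer, _BatchNorm):
                layer.running_mean = h.mean(axis=(0, 2, 3))
                layer.running_var = h.var(axis=(0, 2, 3))
            h = layer.forward(h, False)

    def train_step(
        self, x: np.ndarray, y: np.ndarray, lr: float, weight_decay: float = 0.0
    ) -> float:
        for p in self.params:
            p.grad[...] = 0.0
        logits = self.forward(x, train=True)
        probs = _softmax(logits)
        n = x.shape[0]
        loss = -float(np.mean(np.log(probs[np.arange(n), y] + 1e-12)))
        if not np.isfinite(loss):
            raise ValidationError("training loss is non-finite")
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        self._backward(dlogits / n)
        self._t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            mhat = p.m / (1 - b1**self._t)
            vhat = p.v / (1 - b2**self._t)
            p.value -= lr * (mhat / (np.sqrt(vhat) + eps) + weight_decay * p.value)
        return loss

    def loss_accuracy(self, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        probs = self.predict_proba(x)
        loss = -float(np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))
        acc = 100.0 * int(np.sum(np.argmax(probs, axis=1) == y)) / len(y)
        return loss, acc


def build_cnn(
    d: int, n_classes: int, arch: CNNArchitecture = CNNArchitecture(), seed: int = 0
) -> CNNModel:
    """Construct the model; ``model.shape_report`` lists each block's shape."""
    return CNNModel(d, n_classes, arch, seed=seed)


def stratified_split(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split; every class keeps >= 1 sample on each side."""
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        members = rng.permutation(np.nonzero(labels == c)[0])
        n_test = min(max(int(round(test_fraction * members.size)), 1), members.size - 1)
        test_idx += members[:n_test].tolist()
        train_idx += members[n_test:].tolist()
    return np.sort(train_idx), np.sort(test_idx)


def train_eval_cnn(
    dataset: ExpressionDataset,
    mask: np.ndarray,
    arch: CNNArchitecture = CNNArchitecture(),
    train_config: TrainConfig = TrainConfig(),
) -> tuple[FitnessResult, dict[str, list[float]]]:
    """Train on a stratified split of the masked genes; return held-out
    accuracy plus per-epoch train/test accuracy and loss curves."""
    mask = np.asarray(mask).astype(bool)
    if mask.sum() == 0:
        raise ValidationError("mask must select at least one gene")
    rng = np.random.default_rng(train_config.seed)
    x = dataset.matrix[:, mask]
    y = dataset.labels
    tr, te = stratified_split(y, train_config.test_fraction, rng)
    model = build_cnn(
        int(mask.sum()), dataset.n_classes, arch, seed=int(rng.integers(2**31))
    )
    batch = train_config.batch_size or min(16, tr.size)
    curves: dict[str, list[float]] = {
        "train_acc": [], "test_acc": [], "train_loss": [], "test_loss": []
    }
    for _ in range(train_config.epochs):
        order = rng.permutation(tr)
        for start in range(0, order.size, batch):
            idx = order[start : start + batch]
            if idx.size < 2:  # batch-norm needs more than one sample
                continue
            model.train_step(
                x[idx], y[idx], train_config.learning_rate,
                weight_decay=train_config.weight_decay,
            )
        model.recalibrate_batchnorm(x[tr])
        tr_loss, tr_acc = model.loss_accuracy(x[tr], y[tr])
        te_loss, te_acc = model.loss_accuracy(x[te], y[te])
        curves["train_acc"].append(tr_acc)
        curves["test_acc"].append(te_acc)
        curves["train_loss"].append(tr_loss)
        curves["test_loss"].append(te_loss)
    preds = model.predict(x[te])
    cc = int(np.sum(preds == y[te]))
    result = FitnessResult(
        accuracy=100.0 * cc / te.size, CC=cc, N=int(te.size), per_sample_pred=preds
    )
    return result, curves
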