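"""LKNet: a large-kernel residual 1-D convolutional classifier.

The network is a plain residual stack adapted to low-rate biosignal
envelopes: a learned per-timestep input projection (so 1-channel ECG and
4-channel PCG envelope stacks meet the same residual blocks), ``n_blocks``
residual blocks whose convolutions use a deliberately large kernel (default
15 taps instead of the conventional 3), channel doubling with stride-2
temporal downsampling every ``channel_doubling_every`` blocks, global average
pooling, and a 2-class softmax head.

Everything — convolution, batch normalization, Adam, early stopping — is
implemented directly on numpy arrays.  Forward/backward passes use an
im2col formulation so the heavy lifting is matrix multiplication.  All
training randomness (initialization, batch order, validation split) flows
from the seed in :class:`TrainConfig`, so a fixed seed and data order give
identical final weights.

Frozen blocks (used by the transfer-learning protocol) are excluded from
optimizer updates and their batch-norm layers run in inference mode, so
their parameters and buffers stay bit-identical through any number of
training steps.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import ConfigError, DataError
from .features import EnvelopeStack

__all__ = [
    "LKNetSpec",
    "TrainConfig",
    "TrainedModel",
    "build_lknet",
    "train",
    "predict",
    "save_model",
    "load_model",
]

_DTYPE = np.float32


@dataclass(frozen=True)
class LKNetSpec:
    """Architecture hyperparameters.

    ``kernel_size`` must be odd and >= 9 (that is what makes the kernel
    "large"); channels double — with a stride-2 temporal downsampling — every
    ``channel_doubling_every`` blocks.  ``input_adapter`` is ``"fc"`` for a
    per-timestep linear projection (kernel 1) or ``"conv"`` for a full-width
    convolutional adapter.
    """

    input_channels: int
    input_length: int
    n_blocks: int = 8
    kernel_size: int = 15
    base_channels: int = 32
    channel_doubling_every: int = 2
    n_classes: int = 2
    input_adapter: str = "fc"

    def validate(self) -> None:
        if self.kernel_size < 9 or self.kernel_size % 2 == 0:
            raise ConfigError("kernel_size must be odd and >= 9")
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if self.base_channels < 1:
            raise ConfigError("base_channels must be >= 1")
        if self.channel_doubling_every < 1:
            raise ConfigError("channel_doubling_every must be >= 1")
        if self.input_channels < 1:
            raise ConfigError("input_channels must be >= 1")
        if self.input_adapter not in ("fc", "conv"):
            raise ConfigError("input_adapter must be 'fc' or 'conv'")
        n_down = self.n_downsamples()
        if self.input_length < 2**n_down:
            raise ConfigError(
                f"input_length must be >= 2^{n_down} for {n_down} stride-2 stages"
            )

    def n_downsamples(self, n_blocks: int | None = None) -> int:
        nb = self.n_blocks if n_blocks is None else n_blocks
        return sum(1 for i in range(1, nb) if i % self.channel_doubling_every == 0)

    def block_width(self, i: int) -> int:
        """Channel width of block ``i`` under the doubling schedule."""
        return self.base_channels * 2 ** (i // self.channel_doubling_every)

    def block_stride(self, i: int) -> int:
        return 2 if (i > 0 and i % self.channel_doubling_every == 0) else 1


@dataclass(frozen=True)
class TrainConfig:
    """Supervised-training hyperparameters (Adam + cross-entropy)."""

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    early_stop_patience: int = 10
    seed: int = 0
    class_weighting: str = "none"  # none | balanced
    val_fraction: float = 0.2

    def validate(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ConfigError("epochs must be >= 0 and batch_size >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ConfigError("learning_rate must be > 0 and weight_decay >= 0")
        if self.early_stop_patience < 1:
            raise ConfigError("early_stop_patience must be >= 1")
        if self.class_weighting not in ("none", "balanced"):
            raise ConfigError("class_weighting must be 'none' or 'balanced'")
        if not 0 <= self.val_fraction < 1:
            raise ConfigError("val_fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = value.astype(_DTYPE)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


class Conv1d:
    """Same-padded strided 1-D convolution via im2col."""

    def __init__(self, rng, c_in: int, c_out: int, k: int, stride: int = 1):
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        std = np.sqrt(2.0 / (c_in * k))
        self.w = Param(rng.normal(0, std, (c_out, c_in * k)).astype(_DTYPE))
        self.b = Param(np.zeros(c_out, dtype=_DTYPE))

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        windows = windows[:, :, :: self.stride, :]  # (B, C_in, L_out, K)
        b_, _, l_out, _ = windows.shape
        cols = windows.transpose(0, 2, 1, 3).reshape(b_, l_out, self.c_in * self.k)
        self._cols = cols if training else None
        self._in_len = x.shape[2]
        y = cols @ self.w.value.T + self.b.value
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b_, _, l_out = dy.shape
        dyt = dy.transpose(0, 2, 1)  # (B, L_out, C_out)
        flat_dy = dyt.reshape(-1, self.c_out)
        flat_cols = self._cols.reshape(-1, self.c_in * self.k)
        self.w.grad += flat_dy.T @ flat_cols
        self.b.grad += flat_dy.sum(axis=0)
        dcols = (dyt @ self.w.value).reshape(b_, l_out, self.c_in, self.k)
        dcols = dcols.transpose(0, 2, 1, 3)  # (B, C_in, L_out, K)
        pad = self.k // 2
        dxp = np.zeros((b_, self.c_in, self._in_len + 2 * pad), dtype=_DTYPE)
        for kk in range(self.k):
            dxp[:, :, kk : kk + self.stride * l_out : self.stride] += dcols[:, :, :, kk]
        return dxp[:, :, pad : pad + self._in_len]


class BatchNorm1d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c, dtype=_DTYPE))
        self.beta = Param(np.zeros(c, dtype=_DTYPE))
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self.momentum, self.eps = momentum, eps
        self.frozen = False  # frozen -> inference statistics, no buffer updates
        self.calibrating = False  # one-shot exact stats pass after training

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        # frozen layers never use batch statistics during training, but they
        # do participate in calibration: normalization buffers are domain
        # statistics, not learned parameters, and adapting them to the
        # target domain is what makes frozen source blocks well-scaled there
        use_batch = self.calibrating or (training and not self.frozen)
        if use_batch:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            if self.calibrating:
                self.running_mean = mean.astype(_DTYPE)
                self.running_var = var.astype(_DTYPE)
            else:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * invstd[:, None]
        self._cache = (xhat, invstd, use_batch)
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, use_batch = self._cache
        dgamma = (dy * xhat).sum(axis=(0, 2))
        dbeta = dy.sum(axis=(0, 2))
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        g = self.gamma.value[:, None] * invstd[:, None]
        if not use_batch:
            return g * dy
        n = dy.shape[0] * dy.shape[2]
        return (g / n) * (n * dy - dbeta[:, None] - xhat * dgamma[:, None])


class ReLU:
    def params(self):
        return []

    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class ResidualBlock:
    """[conv-bn-relu-conv-bn] + identity-or-projected skip, then ReLU."""

    def __init__(self, rng, c_in: int, c_out: int, k: int, stride: int):
        self.conv1 = Conv1d(rng, c_in, c_out, k, stride)
        self.bn1 = BatchNorm1d(c_out)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(rng, c_out, c_out, k, 1)
        self.bn2 = BatchNorm1d(c_out)
        self.project = c_in != c_out or stride != 1
        if self.project:
            self.skip_conv = Conv1d(rng, c_in, c_out, 1, stride)
            self.skip_bn = BatchNorm1d(c_out)
        self.relu_out = ReLU()

    def layers(self):
        out = [("conv1", self.conv1), ("bn1", self.bn1), ("conv2", self.conv2), ("bn2", self.bn2)]
        if self.project:
            out += [("skip_conv", self.skip_conv), ("skip_bn", self.skip_bn)]
        return out

    def params(self):
        return [(f"{ln}.{pn}", p) for ln, layer in self.layers() for pn, p in layer.params()]

    def set_frozen(self, frozen: bool):
        for _, layer in self.layers():
            if isinstance(layer, BatchNorm1d):
                layer.frozen = frozen
            for _, p in layer.params():
                p.trainable = not frozen

    def forward(self, x, training):
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        if self.project:
            s = self.skip_conv.forward(x, training)
            s = self.skip_bn.forward(s, training)
        else:
            s = x
        return self.relu_out.forward(h + s, training)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dh, ds = d, d
        dh = self.bn2.backward(dh)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.project:
            ds = self.skip_bn.backward(ds)
            dx = dx + self.skip_conv.backward(ds)
        else:
            dx = dx + ds
        return dx


class Linear:
    def __init__(self, rng, n_in: int, n_out: int):
        std = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0, std, (n_out, n_in)).astype(_DTYPE))
        self.b = Param(np.zeros(n_out, dtype=_DTYPE))

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dy):
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value


class LKNet:
    """The assembled network.  Built by :func:`build_lknet`."""

    def __init__(self, spec: LKNetSpec, seed: int = 0, widths: list[int] | None = None,
                 strides: list[int] | None = None):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.widths = widths or [spec.block_width(i) for i in range(spec.n_blocks)]
        self.strides = strides or [spec.block_stride(i) for i in range(spec.n_blocks)]
        adapter_k = 1 if spec.input_adapter == "fc" else spec.kernel_size
        self.adapter = Conv1d(rng, spec.input_channels, self.widths[0], adapter_k, 1)
        self.blocks: list[ResidualBlock] = []
        c_prev = self.widths[0]
        for w, s in zip(self.widths, self.strides):
            self.blocks.append(ResidualBlock(rng, c_prev, w, spec.kernel_size, s))
            c_prev = w
        self.head = Linear(rng, c_prev, spec.n_classes)
        self.frozen_blocks: frozenset[int] = frozenset()

    # -- parameter access ---------------------------------------------------
    def named_params(self):
        out = [(f"adapter.{n}", p) for n, p in self.adapter.params()]
        for i, blk in enumerate(self.blocks):
            out += [(f"block{i}.{n}", p) for n, p in blk.params()]
        out += [(f"head.{n}", p) for n, p in self.head.params()]
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for _, p in self.named_params())

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {n: p.value.copy() for n, p in self.named_params()}
        for i, blk in enumerate(self.blocks):
            for ln, layer in blk.layers():
                if isinstance(layer, BatchNorm1d):
                    d[f"block{i}.{ln}.running_mean"] = layer.running_mean.copy()
                    d[f"block{i}.{ln}.running_var"] = layer.running_var.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        params = dict(self.named_params())
        for name, val in d.items():
            if name in params:
                params[name].value = val.astype(_DTYPE).copy()
            elif name.endswith(("running_mean", "running_var")):
                i = int(name.split(".")[0].removeprefix("block"))
                ln = name.split(".")[1]
                layer = dict(self.blocks[i].layers())[ln]
                setattr(layer, name.split(".")[2], val.astype(_DTYPE).copy())

    def set_frozen_blocks(self, indices) -> None:
        self.frozen_blocks = frozenset(int(i) for i in indices)
        bad = [i for i in self.frozen_blocks if not 0 <= i < len(self.blocks)]
        if bad:
            raise ConfigError(f"frozen block indices out of range: {bad}")
        for i, blk in enumerate(self.blocks):
            blk.set_frozen(i in self.frozen_blocks)

    # -- computation --------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.adapter.forward(x.astype(_DTYPE), training)
        for blk in self.blocks:
            h = blk.forward(h, training)
        self._pool_len = h.shape[2]
        pooled = h.mean(axis=2)
        logits = self.head.forward(pooled, training)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    def backward_from_probs(self, probs, y_idx, sample_w):
        n = probs.shape[0]
        d = probs.copy()
        d[np.arange(n), y_idx] -= 1.0
        d *= sample_w[:, None] / sample_w.sum()
        dpool = self.head.backward(d.astype(_DTYPE))
        dh = np.repeat(dpool[:, :, None], self._pool_len, axis=2) / self._pool_len
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        self.adapter.backward(dh)

    def zero_grad(self):
        for _, p in self.named_params():
            p.grad[...] = 0.0

    def calibrate_bn(self, x: np.ndarray, max_samples: int = 512) -> None:
        """Set batch-norm statistics exactly from one data pass.

        Exponential running averages lag the final weights, and the gap
        compounds through depth; a single calibration pass over (a capped,
        deterministic subset of) the training data pins the inference
        statistics to the trained network.  Frozen blocks participate too:
        their weights stay bit-frozen, but their normalization statistics
        adapt to the data domain actually flowing through them.
        """
        bns = [
            layer
            for blk in self.blocks
            for _, layer in blk.layers()
            if isinstance(layer, BatchNorm1d)
        ]
        for bn in bns:
            bn.calibrating = True
        try:
            self.forward(x[:max_samples].astype(_DTYPE), training=False)
        finally:
            for bn in bns:
                bn.calibrating = False


def build_lknet(spec: LKNetSpec, seed: int = 0) -> LKNet:
    """Construct an untrained LKNet; identical seeds give identical weights."""
    return LKNet(spec, seed=seed)


def expected_parameter_count(spec: LKNetSpec) -> int:
    """Closed-form parameter count for a network built from ``spec``."""
    k = spec.kernel_size

    def conv(c_in, c_out, kk):
        return c_in * kk * c_out + c_out

    def bn(c):
        return 2 * c

    widths = [spec.block_width(i) for i in range(spec.n_blocks)]
    strides = [spec.block_stride(i) for i in range(spec.n_blocks)]
    total = conv(spec.input_channels, widths[0], 1 if spec.input_adapter == "fc" else k)
    c_prev = widths[0]
    for w, s in zip(widths, strides):
        total += conv(c_prev, w, k) + bn(w) + conv(w, w, k) + bn(w)
        if c_prev != w or s != 1:
            total += conv(c_prev, w, 1) + bn(w)
        c_prev = w
    total += c_prev * spec.n_classes + spec.n_classes
    return total


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A trained (or partially trained) LKNet with its training history."""

    net: LKNet
    spec: LKNetSpec
    history: list = field(default_factory=list)
    frozen_block_indices: frozenset = field(default_factory=frozenset)
    meta: dict = field(default_factory=dict)


class Adam:
    def __init__(self, params, lr, weight_decay=0.0, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = [p for _, p in params if p.trainable]
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.wd * p.value
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_DTYPE)


def _coerce_inputs(data) -> tuple[np.ndarray, np.ndarray]:
    """(EnvelopeStack | array, label) pairs -> X (N,C,L) float32, y (N,) int."""
    xs, ys = [], []
    for item, label in data:
        arr = item.channels if isinstance(item, EnvelopeStack) else np.asarray(item)
        if arr.ndim == 1:
            arr = arr[None, :]
        xs.append(arr.astype(_DTYPE))
        ys.append(label)
    if not xs:
        raise DataError("empty training data")
    lens = {a.shape for a in xs}
    if len(lens) != 1:
        raise DataError(f"inputs must share one shape, got {sorted(lens)}")
    y = np.array([_label_index(l) for l in ys], dtype=np.int64)
    return np.stack(xs), y


def _label_index(label) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label)
    mapping = {"normal": 0, "abnormal": 1, "af": 1}
    if label not in mapping:
        raise DataError(f"unknown label {label!r}")
    return mapping[label]


def _macc_from_preds(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    se_den = np.sum(y_true == 1)
    sp_den = np.sum(y_true == 0)
    se = np.sum((y_true == 1) & (y_pred == 1)) / se_den if se_den else 0.0
    sp = np.sum((y_true == 0) & (y_pred == 0)) / sp_den if sp_den else 0.0
    return float((se + sp) / 2)


def train(
    model: LKNet | TrainedModel,
    data,
    cfg: TrainConfig,
    sample_weights: np.ndarray | None = None,
) -> TrainedModel:
    """Train with Adam + cross-entropy, early-stopping on validation MAcc.

    ``data`` is a sequence of (EnvelopeStack or raw array, label) pairs.
    Optional ``sample_weights`` (used by boosting) turn mini-batch selection
    into weighted sampling with replacement.  Parameters of frozen blocks are
    untouched bit-for-bit.  Weights from the best validation epoch are
    restored at the end.
    """
    cfg.validate()
    net = model.net if isinstance(model, TrainedModel) else model
    x, y = _coerce_inputs(data)
    if np.unique(y).size < 2:
        raise DataError("training data must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    n = x.shape[0]

    # stratified validation split
    val_idx = np.zeros(n, dtype=bool)
    if cfg.val_fraction > 0:
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            k = max(int(round(cfg.val_fraction * idx.size)), 1)
            val_idx[rng.permutation(idx)[:k]] = True
        if val_idx.all() or not val_idx.any():
            val_idx[:] = False
    tr = np.flatnonzero(~val_idx)
    va = np.flatnonzero(val_idx)

    w = np.ones(n) if sample_weights is None else np.asarray(sample_weights, dtype=np.float64).copy()
    if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
        raise DataError("sample_weights must be non-negative with positive sum")
    loss_w = np.ones(n)
    if cfg.class_weighting == "balanced":
        for cls in np.unique(y):
            loss_w[y == cls] = n / (2.0 * np.sum(y == cls))

    opt = Adam(net.named_params(), cfg.learning_rate, cfg.weight_decay)
    history: list[dict] = []
    best_state, best_macc, best_epoch, since_best = None, -np.inf, -1, 0
    if cfg.epochs > 0:
        # align normalization statistics (incl. any frozen transferred
        # blocks') with this dataset before the first update
        net.calibrate_bn(x[tr])

    for epoch in range(cfg.epochs):
        if sample_weights is None:
            order = rng.permutation(tr)
        else:
            p = w[tr] / w[tr].sum()
            order = rng.choice(tr, size=tr.size, replace=True, p=p)
        ep_loss, ep_correct, ep_n = 0.0, 0, 0
        for start in range(0, order.size, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            probs = net.forward(x[idx], training=True)
            bw = loss_w[idx]
            ll = -np.log(probs[np.arange(idx.size), y[idx]] + 1e-12)
            ep_loss += float(np.sum(bw * ll))
            ep_correct += int(np.sum(probs.argmax(axis=1) == y[idx]))
            ep_n += idx.size
            net.zero_grad()
            net.backward_from_probs(probs, y[idx], bw)
            opt.step()
        rec = {
            "epoch": epoch,
            "train_loss": ep_loss / max(ep_n, 1),
            "train_acc": ep_correct / max(ep_n, 1),
        }
        net.calibrate_bn(x[tr])
        if va.size:
            vp = predict_probs(net, x[va])
            vm = _macc_from_preds(y[va], vp.argmax(axis=1))
            rec["val_macc"] = vm
        else:
            vm = rec["train_acc"]
        history.append(rec)
        if vm > best_macc + 1e-12:
            best_macc, best_epoch, since_best = vm, epoch, 0
            best_state = net.state_dict()
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)

    return TrainedModel(
        net=net,
        spec=net.spec,
        history=history,
        frozen_block_indices=net.frozen_blocks,
        meta={"best_epoch": best_epoch, "best_val_macc": best_macc if va.size else None},
    )


def predict_probs(net: LKNet, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    out = []
    for start in range(0, x.shape[0], batch_size):
        out.append(net.forward(x[start : start + batch_size].astype(_DTYPE), training=False))
    return np.concatenate(out)


def predict(model: LKNet | TrainedModel, inputs) -> np.ndarray:
    """Per-input class probabilities, deterministic in inference mode.

    ``inputs`` may be an (N, C, L) array, a single (C, L) array, or a list of
    EnvelopeStacks / arrays.
    """
    net = model.net if isinstance(model, TrainedModel) else model
    if isinstance(inputs, np.ndarray):
        x = inputs[None, ...] if inputs.ndim == 2 else inputs
    else:
        x = np.stack(
            [i.channels if isinstance(i, EnvelopeStack) else np.asarray(i) for i in inputs]
        )
    if x.ndim != 3 or x.shape[1] != net.spec.input_channels:
        raise DataError(
            f"input shape {x.shape} incompatible with spec "
            f"(expected (*, {net.spec.input_channels}, L))"
        )
    return predict_probs(net, x.astype(_DTYPE))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(tm: TrainedModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", **tm.net.state_dict())
    meta = {
        "spec": asdict(tm.spec),
        "widths": tm.net.widths,
        "strides": tm.net.strides,
        "frozen_block_indices": sorted(tm.frozen_block_indices),
        "history": tm.history,
        "meta": {k: v for k, v in tm.meta.items() if not isinstance(v, np.ndarray)},
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2, default=float))


def load_model(in_dir: str | Path) -> TrainedModel:
    ind = Path(in_dir)
    meta = json.loads((ind / "model.json").read_text())
    spec = LKNetSpec(**meta["spec"])
    net = LKNet(spec, seed=0, widths=meta["widths"], strides=meta["strides"])
    with np.load(ind / "weights.npz") as z:
        net.load_state_dict({k: z[k] for k in z.files})
    net.set_frozen_blocks(meta["frozen_block_indices"])
    return TrainedModel(
        net=net,
        spec=spec,
        history=meta["history"],
        frozen_block_indices=frozenset(meta["frozen_block_indices"]),
        meta=meta["meta"],
    )
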