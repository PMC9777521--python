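"""Runnable AID-U-Net models and the training loop, in pure NumPy.

A planned :class:`~aidunet.archspec.LayerGraph` is materialized into a model
whose forward pass maps a batch ``(N, C, *spatial)`` of patches to per-pixel
class probabilities of identical spatial extent.  All layers (same-padded
convolutions, 2x max-pooling, stride-2 transposed convolutions, batch
normalization with trainable scale/shift, dropout, channel concatenation,
softmax head) carry hand-written backward passes, so the package trains
end-to-end on a CPU with no deep-learning framework.

Merging by concatenation rather than addition is deliberate: the channel-wise
variance of a concatenated map equals that of its inputs, whereas adding two
independent maps doubles it — concatenation therefore keeps activations on a
stable scale through the decoder.

Convolutions are evaluated by shift-and-multiply: one batched channel-mixing
matmul per kernel offset.  This keeps memory flat and works identically in
2D and 3D.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .archspec import ArchConfig, LayerGraph, count_parameters, plan_layers
from .losses_metrics import DICE_EPS

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "AidUNet",
    "build_model",
    "train",
    "predict_mask",
]


# ---------------------------------------------------------------------------
# Parameters and primitive layers
# ---------------------------------------------------------------------------

class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _spatial_axes(ndim: int) -> tuple[int, ...]:
    return tuple(range(2, ndim))


class Conv:
    """Same-padded convolution, stride 1, odd (or 1) kernel."""

    def __init__(self, in_ch, out_ch, kernel, dims, rng):
        fan_in = in_ch * kernel ** dims
        self.kernel, self.dims = kernel, dims
        self.in_ch, self.out_ch = in_ch, out_ch
        self.W = Param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_ch, in_ch) + (kernel,) * dims)
        )
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        pad = self.kernel // 2
        spatial = x.shape[2:]
        if pad:
            xp = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * self.dims)
        else:
            xp = x
        n = x.shape[0]
        npix = int(np.prod(spatial))
        yf = np.zeros((n, self.out_ch, npix), dtype=np.float32)
        for idx in product(range(self.kernel), repeat=self.dims):
            sl = (slice(None), slice(None)) + tuple(
                slice(i, i + s) for i, s in zip(idx, spatial)
            )
            xs = xp[sl].reshape(n, self.in_ch, npix)
            wk = self.W.value[(slice(None), slice(None)) + idx]
            yf += wk[None] @ xs
        y = yf.reshape((n, self.out_ch) + spatial)
        y += self.b.value.reshape((1, -1) + (1,) * self.dims)
        self._cache = (xp, spatial)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, spatial = self._cache
        pad = self.kernel // 2
        n = dy.shape[0]
        npix = int(np.prod(spatial))
        dyf = dy.reshape(n, self.out_ch, npix)
        self.b.grad += dy.sum(axis=(0,) + _spatial_axes(dy.ndim))
        dxp = np.zeros_like(xp)
        for idx in product(range(self.kernel), repeat=self.dims):
            sl = (slice(None), slice(None)) + tuple(
                slice(i, i + s) for i, s in zip(idx, spatial)
            )
            xs = xp[sl].reshape(n, self.in_ch, npix)
            self.W.grad[(slice(None), slice(None)) + idx] += np.tensordot(
                dyf, xs, axes=([0, 2], [0, 2])
            )
            wk = self.W.value[(slice(None), slice(None)) + idx]
            dxp[sl] += (wk.T[None] @ dyf).reshape((n, self.in_ch) + spatial)
        if pad:
            center = (slice(None), slice(None)) + tuple(
                slice(pad, pad + s) for s in spatial
            )
            return dxp[center]
        return dxp


class ConvTranspose:
    """Transposed convolution with kernel 2 and stride 2 (non-overlapping):
    each input voxel expands into a 2**dims block."""

    def __init__(self, in_ch, out_ch, dims, rng):
        self.dims = dims
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in = in_ch
        self.W = Param(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(in_ch, out_ch) + (2,) * dims)
        )
        self.b = Param(np.zeros(out_ch))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _interleave_perm(self):
        d = self.dims
        # tmp axes: N, S1..Sd, Cout, k1..kd  ->  N, Cout, S1,k1, S2,k2, ...
        perm = [0, d + 1]
        for i in range(d):
            perm += [1 + i, d + 2 + i]
        return perm

    def forward(self, x: np.ndarray) -> np.ndarray:
        n = x.shape[0]
        spatial = x.shape[2:]
        tmp = np.tensordot(x, self.W.value, axes=([1], [0]))
        tmp = np.transpose(tmp, self._interleave_perm())
        y = tmp.reshape((n, self.out_ch) + tuple(2 * s for s in spatial))
        y = np.ascontiguousarray(y, dtype=np.float32)
        y += self.b.value.reshape((1, -1) + (1,) * self.dims)
        self._cache = (x, spatial)
        return y

    def _fold(self, dy: np.ndarray, spatial) -> np.ndarray:
        """dy (N, Cout, *2S) -> (N, *S, Cout, *k) matching forward's tmp."""
        n = dy.shape[0]
        shape = (n, self.out_ch)
        for s in spatial:
            shape += (s, 2)
        dyv = dy.reshape(shape)
        perm = self._interleave_perm()
        inv = np.argsort(perm)
        return np.transpose(dyv, inv)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, spatial = self._cache
        d = self.dims
        self.b.grad += dy.sum(axis=(0,) + _spatial_axes(dy.ndim))
        dyt = np.ascontiguousarray(self._fold(dy, spatial))  # (N,*S,Cout,*k)
        batch_axes = list(range(1 + d))  # N plus spatial
        self.W.grad += np.tensordot(x, dyt, axes=([0] + list(range(2, 2 + d)),
                                                  batch_axes))
        dx = np.tensordot(dyt, self.W.value,
                          axes=(list(range(1 + d, 1 + 2 * d + 1)),
                                list(range(1, 2 + d))))
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1), dtype=np.float32)


class BatchNorm:
    """Batch normalization over batch and spatial axes with trainable
    per-channel scale (gamma) and shift (beta); running statistics are kept
    for inference and are not trainable."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0,) + _spatial_axes(x.ndim)
        shape = (1, -1) + (1,) * (x.ndim - 2)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        y = self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)
        self._cache = (xhat, inv_std, axes, shape, x.shape)
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape, xshape = self._cache
        m = np.prod([xshape[a] for a in axes])
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
        ) * inv_std.reshape(shape)
        return dx.astype(np.float32)


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class Dropout:
    """Inverted dropout; identity outside training or at rate 0."""

    def __init__(self, rate):
        self.rate = rate
        self._mask = None

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class MaxPool:
    """2x max-pooling with stride 2 in every spatial axis."""

    def __init__(self, dims):
        self.dims = dims
        self._cache = None

    def _windows(self, x):
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        shape = (n, c)
        for s in spatial:
            shape += (s // 2, 2)
        xv = x.reshape(shape)
        # move the window axes (3, 5, ...) to the end
        perm = [0, 1] + [2 + 2 * i for i in range(self.dims)] + [
            3 + 2 * i for i in range(self.dims)
        ]
        xt = np.transpose(xv, perm)
        out_spatial = tuple(s // 2 for s in spatial)
        return xt.reshape((n, c) + out_spatial + (2 ** self.dims,)), out_spatial

    def forward(self, x):
        win, out_spatial = self._windows(x)
        arg = win.argmax(axis=-1)
        y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
        self._cache = (arg, x.shape, out_spatial)
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, dy):
        arg, xshape, out_spatial = self._cache
        n, c = xshape[:2]
        dwin = np.zeros((n, c) + out_spatial + (2 ** self.dims,), dtype=np.float32)
        np.put_along_axis(dwin, arg[..., None], dy[..., None], axis=-1)
        # invert the window flattening
        shape = (n, c) + out_spatial + (2,) * self.dims
        dwin = dwin.reshape(shape)
        perm = [0, 1] + [2 + 2 * i for i in range(self.dims)] + [
            3 + 2 * i for i in range(self.dims)
        ]
        inv = np.argsort(perm)
        dx = np.transpose(dwin, inv).reshape(xshape)
        return np.ascontiguousarray(dx, dtype=np.float32)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class _Block:
    """Materialized counterpart of one archspec BlockSpec."""

    def __init__(self, spec, config: ArchConfig, rng):
        self.spec = spec
        dims = config.dims
        self.pool = MaxPool(dims) if spec.pool_from is not None else None
        self.upconv = None
        self.convs: list[Conv] = []
        self.norms: list[BatchNorm | None] = []
        self.relus: list[ReLU] = []
        for layer in spec.layers:
            if layer.kind == "upconv":
                self.upconv = ConvTranspose(
                    layer.in_channels, layer.out_channels, dims, rng
                )
            else:
                self.convs.append(
                    Conv(layer.in_channels, layer.out_channels, layer.kernel,
                         dims, rng)
                )
                self.norms.append(
                    BatchNorm(layer.out_channels) if layer.batch_norm else None
                )
                self.relus.append(ReLU() if layer.kind == "conv" else None)
        self.dropout = (
            Dropout(config.dropout_rate) if spec.role != "head" else None
        )
        self._concat_split = None

    def params(self):
        out = []
        if self.upconv is not None:
            out += self.upconv.params()
        for conv, norm in zip(self.convs, self.norms):
            out += conv.params()
            if norm is not None:
                out += norm.params()
        return out

    def forward(self, x, skip, training, rng):
        if self.pool is not None:
            x = self.pool.forward(x)
        if self.upconv is not None:
            x = self.upconv.forward(x)
            # channel concat: skip first, then up-convolved features
            self._concat_split = skip.shape[1]
            x = np.concatenate([skip, x], axis=1)
        for conv, norm, relu in zip(self.convs, self.norms, self.relus):
            x = conv.forward(x)
            if norm is not None:
                x = norm.forward(x, training)
            if relu is not None:
                x = relu.forward(x)
        if self.dropout is not None:
            x = self.dropout.forward(x, training, rng)
        return x

    def backward(self, dy):
        """Returns (d_input, d_skip); d_skip is None without a concat."""
        if self.dropout is not None:
            dy = self.dropout.backward(dy)
        for conv, norm, relu in zip(
            reversed(self.convs), reversed(self.norms), reversed(self.relus)
        ):
            if relu is not None:
                dy = relu.backward(dy)
            if norm is not None:
                dy = norm.backward(dy)
            dy = conv.backward(dy)
        dskip = None
        if self.upconv is not None:
            split = self._concat_split
            dskip = dy[:, :split]
            dy = self.upconv.backward(np.ascontiguousarray(dy[:, split:]))
        if self.pool is not None:
            dy = self.pool.backward(dy)
        return dy, dskip


class AidUNet:
    """A trainable AID-U-Net materialized from a :class:`LayerGraph`."""

    def __init__(self, graph: LayerGraph, seed: int = 0):
        self.graph = graph
        self.config = graph.config
        rng = np.random.default_rng(seed)
        self.blocks = [_Block(spec, graph.config, rng) for spec in graph.blocks]
        planned = count_parameters(graph)
        actual = self.num_parameters()
        if planned != actual:
            raise RuntimeError(
                f"materialized parameter count {actual} disagrees with the "
                f"planned count {planned}"
            )

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> list[Param]:
        out = []
        for block in self.blocks:
            out += block.params()
        return out

    def num_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def _norm_layers(self) -> list[BatchNorm]:
        out = []
        for block in self.blocks:
            out += [n for n in block.norms if n is not None]
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        """Trainable parameters plus batch-norm running statistics, keyed in
        deterministic order for checkpointing."""
        state = {
            f"param_{i}": p.value for i, p in enumerate(self.parameters())
        }
        for i, norm in enumerate(self._norm_layers()):
            state[f"running_mean_{i}"] = norm.running_mean
            state[f"running_var_{i}"] = norm.running_var
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            value = np.asarray(state[f"param_{i}"], dtype=np.float32)
            if value.shape != p.value.shape:
                raise ValueError(f"checkpoint shape mismatch at param_{i}")
            p.value = value
            p.grad = np.zeros_like(value)
        for i, norm in enumerate(self._norm_layers()):
            norm.running_mean = np.asarray(
                state[f"running_mean_{i}"], dtype=np.float32
            )
            norm.running_var = np.asarray(
                state[f"running_var_{i}"], dtype=np.float32
            )

    # -- execution ----------------------------------------------------------
    def _check_input(self, x: np.ndarray):
        cfg = self.config
        if x.ndim != cfg.dims + 2:
            raise ValueError(
                f"expected batch of rank {cfg.dims + 2} (N, C, *spatial), "
                f"got {x.ndim}"
            )
        if x.shape[1] != cfg.in_channels:
            raise ValueError(
                f"expected {cfg.in_channels} channels, got {x.shape[1]}"
            )
        if tuple(x.shape[2:]) != cfg.input_extent:
            raise ValueError(
                f"expected spatial extent {cfg.input_extent}, got {x.shape[2:]}"
            )

    def forward_logits(self, x: np.ndarray, training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        """Class scores before softmax, shape (N, num_classes, *spatial)."""
        self._check_input(x)
        if rng is None:
            rng = np.random.default_rng(0)
        x = np.ascontiguousarray(x, dtype=np.float32)
        outputs: dict[int, np.ndarray] = {}
        y = None
        for block in self.blocks:
            spec = block.spec
            if spec.pool_from is not None:
                inp = outputs[spec.pool_from]
            elif spec.upconv_from is not None:
                inp = outputs[spec.upconv_from]
            elif spec.role == "head":
                inp = outputs[len(self.blocks) - 2]
            else:
                inp = x
            skip = outputs[spec.concat_with] if spec.concat_with is not None else None
            y = block.forward(inp, skip, training, rng)
            outputs[spec.index] = y
        return y

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-pixel class probabilities (softmax over the class axis)."""
        return softmax(self.forward_logits(x, training, rng))

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the head logits into all params."""
        grads: dict[int, np.ndarray] = {len(self.blocks) - 1: dlogits}
        for block in reversed(self.blocks):
            spec = block.spec
            dy = grads.pop(spec.index, None)
            if dy is None:
                continue
            dinp, dskip = block.backward(dy)
            if dskip is not None:
                _accumulate(grads, spec.concat_with, dskip)
            if spec.pool_from is not None:
                _accumulate(grads, spec.pool_from, dinp)
            elif spec.upconv_from is not None:
                _accumulate(grads, spec.upconv_from, dinp)
            elif spec.role == "head":
                _accumulate(grads, len(self.blocks) - 2, dinp)
            # else: first contracting block; gradient w.r.t. input discarded


def _accumulate(grads: dict, key: int, value: np.ndarray):
    if key in grads:
        grads[key] = grads[key] + value
    else:
        grads[key] = value


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def build_model(graph: LayerGraph, seed: int = 0) -> AidUNet:
    """Materialize a planned layer graph as a runnable, trainable model."""
    return AidUNet(graph, seed=seed)


# ---------------------------------------------------------------------------
# Losses (value + gradient w.r.t. logits)
# ---------------------------------------------------------------------------

def _one_hot_batch(masks: np.ndarray, num_classes: int) -> np.ndarray:
    out = np.zeros((masks.shape[0], num_classes) + masks.shape[1:], dtype=np.float32)
    for c in range(num_classes):
        out[:, c] = masks == c
    return out


def dice_loss_and_grad(logits: np.ndarray, masks: np.ndarray,
                       eps: float = DICE_EPS) -> tuple[float, np.ndarray]:
    """Generalized dice loss over the batch and its gradient w.r.t. logits.

    Class weights are the inverse squared class areas of the batch ground
    truth; batch and spatial axes together form the element axis.
    """
    p = softmax(logits)
    num_classes = logits.shape[1]
    g = _one_hot_batch(masks, num_classes)
    axes = (0,) + _spatial_axes(logits.ndim)
    # one-hot G means sum G^2 = sum G, so the inverse-squared-area weight is
    # the reciprocal of the class element count; absent classes get weight 0
    area = g.sum(axis=axes, dtype=np.float64)
    w = np.where(area > 0, 1.0 / np.maximum(area, 1.0), 0.0)
    inter = (p * g).sum(axis=axes, dtype=np.float64)
    sq = (p.astype(np.float64) ** 2 + g).sum(axis=axes)
    num = 2.0 * float((w * inter).sum()) + eps
    den = float((w * sq).sum()) + eps
    loss = 1.0 - num / den
    shape = (1, -1) + (1,) * (logits.ndim - 2)
    wv = w.reshape(shape)
    dP = -(2.0 * wv * g * den - num * 2.0 * wv * p) / den ** 2
    dZ = p * (dP - (dP * p).sum(axis=1, keepdims=True))
    return loss, dZ.astype(np.float32)


def cross_entropy_loss_and_grad(logits: np.ndarray,
                                masks: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-pixel softmax cross-entropy and its logit gradient."""
    p = softmax(logits)
    num_classes = logits.shape[1]
    g = _one_hot_batch(masks, num_classes)
    n_el = masks.size
    loss = float(-(g * np.log(np.maximum(p, 1e-12))).sum() / n_el)
    dZ = (p - g) / n_el
    return loss, dZ.astype(np.float32)


_LOSSES = {
    "generalized_dice": dice_loss_and_grad,
    "cross_entropy": cross_entropy_loss_and_grad,
}


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[Param], lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters; the seed fixes shuffling and dropout."""

    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    rng_seed: int = 0
    loss: str = "generalized_dice"
    validation_fraction: float = 0.25

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in _LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")


@dataclass
class TrainHistory:
    """Per-epoch loss and IoU records for train and validation splits."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_iou: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)

    @property
    def epochs_completed(self) -> int:
        return len(self.train_loss)


def _to_batch(samples, config: ArchConfig):
    """Channel-last (image, mask) pairs -> (N, C, *S) float32 and int masks."""
    xs, ys = [], []
    for image, mask in samples:
        image = np.asarray(image)
        if image.ndim == config.dims:  # implicit single channel
            image = image[..., None]
        xs.append(np.moveaxis(image, -1, 0))
        ys.append(np.asarray(mask))
    return (np.stack(xs).astype(np.float32), np.stack(ys).astype(np.int64))


def _foreground_iou(conf: np.ndarray) -> float:
    """Mean IoU of non-background classes from accumulated (C, 3) TP/FP/FN."""
    vals = []
    for c in range(1, conf.shape[0]):
        tp, fp, fn = conf[c]
        if tp + fp + fn > 0:
            vals.append(tp / (tp + fp + fn))
    return float(np.mean(vals)) if vals else float("nan")


def _confusion_update(conf: np.ndarray, pred: np.ndarray, gt: np.ndarray):
    for c in range(conf.shape[0]):
        p = pred == c
        g = gt == c
        conf[c, 0] += np.count_nonzero(p & g)
        conf[c, 1] += np.count_nonzero(p & ~g)
        conf[c, 2] += np.count_nonzero(~p & g)


def train(model: AidUNet, dataset, config: TrainConfig) -> tuple[AidUNet, TrainHistory]:
    """Train ``model`` on channel-last (image, mask) pairs.

    The dataset is shuffled and split into train/validation with the config
    seed; identical seed, config and data order reproduce the history
    bitwise on one machine.  A non-finite loss aborts with the offending
    epoch and batch named.
    """
    rng = np.random.default_rng(config.rng_seed)
    x, y = _to_batch(dataset, model.config)
    n = x.shape[0]
    order = np.random.default_rng(config.rng_seed + 1).permutation(n)
    n_val = max(1, int(round(n * config.validation_fraction))) if n > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        raise ValueError("dataset too small for the requested validation split")
    loss_fn = _LOSSES[config.loss]
    opt = Adam(model.parameters(), lr=config.learning_rate)
    num_classes = model.config.num_classes
    history = TrainHistory()

    for epoch in range(config.epochs):
        perm = train_idx[rng.permutation(train_idx.size)]
        losses, weights = [], []
        conf = np.zeros((num_classes, 3), dtype=np.int64)
        for start in range(0, perm.size, config.batch_size):
            batch = perm[start:start + config.batch_size]
            xb, yb = x[batch], y[batch]
            model.zero_grad()
            logits = model.forward_logits(xb, training=True, rng=rng)
            loss, dz = loss_fn(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, "
                    f"batch {start // config.batch_size}"
                )
            model.backward(dz)
            opt.step()
            losses.append(loss)
            weights.append(len(batch))
            _confusion_update(conf, logits.argmax(axis=1), yb)
        history.train_loss.append(float(np.average(losses, weights=weights)))
        history.train_iou.append(_foreground_iou(conf))

        if val_idx.size:
            vloss, vconf = _evaluate(model, x[val_idx], y[val_idx],
                                     config.batch_size, loss_fn, num_classes)
            history.val_loss.append(vloss)
            history.val_iou.append(_foreground_iou(vconf))
        else:
            history.val_loss.append(float("nan"))
            history.val_iou.append(float("nan"))
    return model, history


def _evaluate(model, x, y, batch_size, loss_fn, num_classes):
    losses, weights = [], []
    conf = np.zeros((num_classes, 3), dtype=np.int64)
    for start in range(0, x.shape[0], batch_size):
        xb, yb = x[start:start + batch_size], y[start:start + batch_size]
        logits = model.forward_logits(xb, training=False)
        loss, _ = loss_fn(logits, yb)
        losses.append(loss)
        weights.append(xb.shape[0])
        _confusion_update(conf, logits.argmax(axis=1), yb)
    return float(np.average(losses, weights=weights)), conf


# ---------------------------------------------------------------------------
# Whole-image prediction
# ---------------------------------------------------------------------------

def predict_mask(model: AidUNet, image: np.ndarray, patch_plan) -> np.ndarray:
    """Segment a full image through its patch plan.

    Patches are run in inference mode; where patches overlap, class
    probabilities are averaged before the argmax.  Pixels outside the crop
    window receive the background label 0.
    """
    from .preprocess import extract_patches

    image = np.asarray(image)
    rank = len(patch_plan.image_extent)
    if image.shape[:rank] != patch_plan.image_extent:
        raise ValueError(
            f"plan extent {patch_plan.image_extent} does not match image "
            f"extent {image.shape[:rank]}"
        )
    num_classes = model.config.num_classes
    scores = np.zeros((num_classes,) + patch_plan.image_extent, dtype=np.float64)
    counts = np.zeros(patch_plan.image_extent, dtype=np.int64)
    patches = extract_patches(image, None, patch_plan)
    for origin, (patch, _) in zip(patch_plan.patch_origins, patches):
        if patch.ndim == rank:
            patch = patch[..., None]
        xb = np.moveaxis(patch, -1, 0)[None].astype(np.float32)
        probs = model.forward(xb, training=False)[0]
        sl = tuple(
            slice(co + o, co + o + p)
            for co, o, p in zip(patch_plan.crop_offset, origin,
                                patch_plan.patch_extent)
        )
        scores[(slice(None),) + sl] += probs
        counts[sl] += 1
    mask = np.zeros(patch_plan.image_extent, dtype=np.int64)
    covered = counts > 0
    if covered.any():
        avg = scores[:, covered] / counts[covered]
        mask[covered] = avg.argmax(axis=0)
    return mask
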