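"""LeNet-style convolutional pixel classifier producing the presegmentation.

The network classifies each pixel from the raw multimodal intensity patch
centered on it (default 17×17, one channel per MRI sequence): alternating
valid convolution + 2×2 pooling blocks, one fully connected layer, and a
Softmax output trained with cross-entropy.  It is a deliberately small,
pure-numpy network — im2col convolutions, Adam updates, explicit
backpropagation — sized so that a full training run on a desk-scale phantom
cohort takes seconds, and seeded so that identical (data, config, seed)
triples give bitwise-identical predictions.

Class imbalance is handled by class-balanced subsampling of the training
pixels: tumor pixels are rare, so the background is down-sampled to match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import features as _features
from .io_formats import CaseRecord, ImageVolume, LabelMap, LabelScheme, Modality, binarize_whole_tumor

__all__ = ["CNNConfig", "CNNModel", "relu", "softplus", "train_cnn",
           "predict_proba", "predict_labels"]

logger = logging.getLogger(__name__)

#: Fixed channel order for multimodal patch stacks.
MODALITY_ORDER = (Modality.T1, Modality.T1CE, Modality.T2, Modality.FLAIR)

#: BraTS code → class index used when n_classes > 2.
_BRATS_TO_CLASS = {0: 0, 1: 1, 2: 2, 4: 3}
_CLASS_TO_BRATS = {v: k for k, v in _BRATS_TO_CLASS.items()}


def relu(x):
    """Rectified linear activation, f(x) = max(0, x)."""
    return np.maximum(0, x)


def softplus(x):
    """Smooth rectifier, f(x) = log(1 + e^x), overflow-safe for large |x|."""
    return np.logaddexp(0, x)


def _act(name: str, x: np.ndarray) -> np.ndarray:
    return relu(x) if name == "relu" else softplus(x)


def _act_grad(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (x > 0).astype(x.dtype)
    # d/dx log(1+e^x) = sigmoid(x)
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class CNNConfig:
    """Architecture and training tunables of the pixel classifier."""

    patch_size: int = 17
    conv_channels: Tuple[int, ...] = (8, 16)
    kernel_size: int = 3
    pool: str = "max"
    activation: str = "relu"
    fc_units: int = 64
    n_classes: int = 2
    epochs: int = 10
    batch_size: int = 128
    learning_rate: float = 1e-3
    max_train_pixels: int = 8000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0 or self.patch_size < 1:
            raise ValueError("patch_size must be odd and positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.pool not in ("max", "mean"):
            raise ValueError("pool must be 'max' or 'mean'")
        if self.activation not in ("relu", "softplus"):
            raise ValueError("activation must be 'relu' or 'softplus'")


@dataclass
class CNNModel:
    """A (possibly trained) pixel classifier: config + weight container."""

    config: CNNConfig
    parameters: Dict[str, np.ndarray] = field(default_factory=dict)
    trained: bool = False
    in_channels: int = 0
    loss_history: List[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# forward / backward primitives


def _conv_forward(x, W, b):
    """Valid cross-correlation. x: (N,C,H,W); W: (C*k*k, F); returns (out, cols)."""
    k = int(np.sqrt(W.shape[0] // x.shape[1]))
    win = sliding_window_view(x, (k, k), axis=(2, 3))      # (N,C,Ho,Wo,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(-1, W.shape[0])
    out = cols @ W + b
    n, _, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
    return out, cols


def _conv_backward(dout, cols, x_shape, W):
    n, c, h, w = x_shape
    k = int(np.sqrt(W.shape[0] // c))
    ho, wo = h - k + 1, w - k + 1
    dflat = dout.transpose(0, 2, 3, 1).reshape(-1, dout.shape[1])
    dW = cols.T @ dflat
    db = dflat.sum(axis=0)
    dcols = (dflat @ W.T).reshape(n, ho, wo, c, k, k)
    dx = np.zeros(x_shape)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + ho, j:j + wo] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx, dW, db


def _pool_forward(x, mode):
    n, c, h, w = x.shape
    ho, wo = h // 2, w // 2
    xc = x[:, :, : ho * 2, : wo * 2].reshape(n, c, ho, 2, wo, 2)
    if mode == "max":
        flat = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        return out, (arg, x.shape)
    out = xc.mean(axis=(3, 5))
    return out, (None, x.shape)


def _pool_backward(dout, cache, mode):
    arg, x_shape = cache
    n, c, h, w = x_shape
    ho, wo = h // 2, w // 2
    dx = np.zeros(x_shape)
    if mode == "max":
        dflat = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dflat, arg[..., None], dout[..., None], axis=-1)
        dx[:, :, : ho * 2, : wo * 2] = (
            dflat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * 2, wo * 2)
        )
    else:
        dx[:, :, : ho * 2, : wo * 2] = np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0
    return dx


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _init_parameters(config: CNNConfig, in_channels: int, rng) -> Dict[str, np.ndarray]:
    params: Dict[str, np.ndarray] = {}
    c, size = in_channels, config.patch_size
    k = config.kernel_size
    for i, f in enumerate(config.conv_channels):
        fan_in = c * k * k
        params[f"Wc{i}"] = rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, f))
        params[f"bc{i}"] = np.zeros(f)
        size = (size - k + 1) // 2
        c = f
    flat = c * size * size
    if flat <= 0:
        raise ValueError("patch_size too small for the configured conv stack")
    params["W1"] = rng.normal(0, np.sqrt(2.0 / flat), size=(flat, config.fc_units))
    params["b1"] = np.zeros(config.fc_units)
    params["W2"] = rng.normal(0, np.sqrt(2.0 / config.fc_units),
                              size=(config.fc_units, config.n_classes))
    params["b2"] = np.zeros(config.n_classes)
    return params


def _forward(params, config, x, need_cache=False):
    cache = {"x": x}
    h = x
    for i in range(len(config.conv_channels)):
        cache[f"in{i}"] = h
        z, cols = _conv_forward(h, params[f"Wc{i}"], params[f"bc{i}"])
        a = _act(config.activation, z)
        p, pc = _pool_forward(a, config.pool)
        cache[f"cols{i}"], cache[f"z{i}"], cache[f"pool{i}"] = cols, z, pc
        h = p
    n = h.shape[0]
    flat = h.reshape(n, -1)
    z1 = flat @ params["W1"] + params["b1"]
    a1 = _act(config.activation, z1)
    z2 = a1 @ params["W2"] + params["b2"]
    probs = _softmax(z2)
    if not need_cache:
        return probs, None
    cache.update(flat=flat, zfc=z1, afc=a1, conv_out_shape=h.shape)
    return probs, cache


def _backward(params, config, probs, y, cache):
    n = probs.shape[0]
    grads = {}
    dz2 = probs.copy()
    dz2[np.arange(n), y] -= 1.0
    dz2 /= n
    grads["W2"] = cache["afc"].T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    da1 = dz2 @ params["W2"].T
    dz1 = da1 * _act_grad(config.activation, cache["zfc"])
    grads["W1"] = cache["flat"].T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    dh = (dz1 @ params["W1"].T).reshape(cache["conv_out_shape"])
    for i in reversed(range(len(config.conv_channels))):
        da = _pool_backward(dh, cache[f"pool{i}"], config.pool)
        dz = da * _act_grad(config.activation, cache[f"z{i}"])
        dh, grads[f"Wc{i}"], grads[f"bc{i}"] = _conv_backward(
            dz, cache[f"cols{i}"], cache[f"in{i}"].shape, params[f"Wc{i}"])
    return grads


class _Adam:
    def __init__(self, params, lr):
        self.lr, self.t = lr, 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# data plumbing


def _case_channel_slices(source: Union[CaseRecord, ImageVolume],
                         normalize: bool = True) -> List[Tuple[np.ndarray, Optional[np.ndarray]]]:
    """Normalize a case/volume into per-slice (channels, truth) pairs.

    Channels follow MODALITY_ORDER (present modalities only); 3-D volumes are
    split slice-wise along the last axis.
    """
    if isinstance(source, ImageVolume):
        vols = [source]
        truth = None
    else:
        vols = [source.volumes[m] for m in MODALITY_ORDER if m in source.volumes]
        if not vols:
            vols = list(source.volumes.values())
        truth = source.truth
    if normalize:
        vols = [_features.normalize_intensity(v) for v in vols]
    stack = np.stack([v.data for v in vols])  # (C, ...) spatial
    tdata = truth.data if truth is not None else None
    if stack.ndim == 3:  # (C, H, W)
        return [(stack, tdata)]
    return [(stack[..., s], tdata[..., s] if tdata is not None else None)
            for s in range(stack.shape[-1])]


def _pad_channels(channels: np.ndarray, half: int) -> np.ndarray:
    return np.pad(channels, ((0, 0), (half, half), (half, half)), mode="reflect")


def _patches_at(channels: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                patch_size: int) -> np.ndarray:
    half = patch_size // 2
    padded = _pad_channels(channels, half)
    win = sliding_window_view(padded, (patch_size, patch_size), axis=(1, 2))
    return win[:, rows, cols].transpose(1, 0, 2, 3)  # (n, C, P, P)


def _truth_classes(truth: LabelMap, n_classes: int) -> np.ndarray:
    if n_classes == 2:
        return binarize_whole_tumor(truth).data
    return np.vectorize(_BRATS_TO_CLASS.__getitem__)(truth.data)


# ---------------------------------------------------------------------------
# public API


def train_cnn(cases: Sequence[CaseRecord], config: Optional[CNNConfig] = None) -> CNNModel:
    """Train the pixel classifier on labeled cases.

    Pools class-balanced patches across all cases/slices (background
    down-sampled to the rarest class, capped at ``max_train_pixels`` total)
    and runs seeded minibatch Adam on the softmax cross-entropy.  With
    ``epochs=0`` the returned model is flagged untrained and prediction
    refuses to run.
    """
    config = config or CNNConfig()
    if not cases:
        raise ValueError("at least one training case required")
    for case in cases:
        if case.truth is None:
            raise ValueError(f"case {case.case_id!r} has no ground truth")

    rng = np.random.default_rng(config.seed)
    all_patches, all_labels = [], []
    in_channels = None
    for case in cases:
        for channels, tdata in _case_channel_slices(case):
            if in_channels is None:
                in_channels = channels.shape[0]
            elif channels.shape[0] != in_channels:
                raise ValueError("all cases must share one modality set")
            classes = _truth_classes(LabelMap(data=tdata, scheme=case.truth.scheme),
                                     config.n_classes)
            all_patches.append((channels, classes))

    # pool pixel coordinates per class over all slices
    per_class: Dict[int, List[Tuple[int, np.ndarray, np.ndarray]]] = {}
    for si, (_, classes) in enumerate(all_patches):
        for cls in range(config.n_classes):
            r, c = np.nonzero(classes == cls)
            if r.size:
                per_class.setdefault(cls, []).append((si, r, c))
    for cls in range(config.n_classes):
        if cls not in per_class:
            raise ValueError(f"class {cls} absent from training pixels")

    counts = {cls: sum(r.size for _, r, _ in lst) for cls, lst in per_class.items()}
    take = min(min(counts.values()), max(1, config.max_train_pixels // config.n_classes))

    xs, ys = [], []
    for cls in range(config.n_classes):
        slice_ids = np.concatenate([np.full(r.size, si) for si, r, _ in per_class[cls]])
        rows = np.concatenate([r for _, r, _ in per_class[cls]])
        cols = np.concatenate([c for _, _, c in per_class[cls]])
        sel = rng.choice(slice_ids.size, size=take, replace=False)
        for si in np.unique(slice_ids[sel]):
            m = slice_ids[sel] == si
            patch = _patches_at(all_patches[si][0], rows[sel][m], cols[sel][m],
                                config.patch_size)
            xs.append(patch)
            ys.append(np.full(patch.shape[0], cls))
    x = np.concatenate(xs)
    y = np.concatenate(ys)

    params = _init_parameters(config, in_channels, rng)
    model = CNNModel(config=config, parameters=params, trained=False, in_channels=in_channels)
    if config.epochs == 0:
        return model

    opt = _Adam(params, config.learning_rate)
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            probs, cache = _forward(params, config, x[idx], need_cache=True)
            loss = -np.mean(np.log(probs[np.arange(idx.size), y[idx]] + 1e-12))
            grads = _backward(params, config, probs, y[idx], cache)
            opt.step(params, grads)
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        model.loss_history.append(epoch_loss)
        logger.info("epoch %d/%d: loss %.4f", epoch + 1, config.epochs, epoch_loss)
    model.trained = True
    return model


def predict_proba(model: CNNModel, source: Union[CaseRecord, ImageVolume],
                  batch_size: int = 512) -> np.ndarray:
    """Per-pixel class probabilities, shape spatial + (n_classes,).

    Patches are extracted with reflect padding so every pixel, including the
    borders, gets a probability vector summing to 1.
    """
    if not model.trained:
        raise RuntimeError("model is not trained")
    slices = _case_channel_slices(source)
    if slices[0][0].shape[0] != model.in_channels:
        raise ValueError(
            f"expected {model.in_channels} channel(s), got {slices[0][0].shape[0]}")
    outs = []
    cfg = model.config
    for channels, _ in slices:
        _, h, w = channels.shape
        half = cfg.patch_size // 2
        padded = _pad_channels(channels, half)
        win = sliding_window_view(padded, (cfg.patch_size, cfg.patch_size), axis=(1, 2))
        probs = np.empty((h * w, cfg.n_classes))
        flat_r, flat_c = np.divmod(np.arange(h * w), w)
        for start in range(0, h * w, batch_size):
            r = flat_r[start:start + batch_size]
            c = flat_c[start:start + batch_size]
            batch = win[:, r, c].transpose(1, 0, 2, 3)
            probs[start:start + batch.shape[0]], _ = _forward(model.parameters, cfg, batch)
        outs.append(probs.reshape(h, w, cfg.n_classes))
    if len(outs) == 1:
        return outs[0]
    return np.stack(outs, axis=2)  # (H, W, D, n_classes)


def predict_labels(model: CNNModel, source: Union[CaseRecord, ImageVolume]) -> LabelMap:
    """Argmax of :func:`predict_proba`; exact ties go to the lower class index."""
    probs = predict_proba(model, source)
    idx = probs.argmax(axis=-1)
    if model.config.n_classes == 2:
        return LabelMap(data=idx.astype(np.int64), scheme=LabelScheme.BINARY)
    codes = np.vectorize(_CLASS_TO_BRATS.__getitem__)(idx)
    return LabelMap(data=codes.astype(np.int64), scheme=LabelScheme.BRATS)
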