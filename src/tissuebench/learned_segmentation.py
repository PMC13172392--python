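"""Trainable tissue segmenter: a desk-scale nested-skip encoder-decoder.

The training protocol mirrors standard practice for binary biomedical
segmentation: pixel-wise binary cross entropy with a positive-class
weight of 5.0, a decoupled-weight-decay Adam optimizer (eps 1e-6, weight
decay 0.01), and early stopping on validation F1 computed over the
global pixel pool.  The recorded default learning rate is 1e-6, suited
to fine-tuning large backbones; desk-scale runs override it (see
``DESK_TRAIN_CONFIG``).

The network itself is a small one-level U-shaped conv net (two 3x3 conv
blocks, a 2x average-pool bottleneck, nearest-neighbour upsampling and a
skip concatenation) implemented directly on NumPy arrays with hand-coded
backpropagation.  A few thousand parameters suffice for tissue/
background discrimination, which is dominated by local color and
texture.

Inference follows the mirror-pad / overlap-discard convention: the
raster is reflect-padded so an integer number of tiles fits, tiles are
predicted at stride ``tile - 2*overlap``, each tile contributes only its
central region (image-border margins are kept, since no neighbour
exists), and every output pixel is written exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .core import (
    MASK_MPP,
    InvalidSpecError,
    NoQualifyingModelError,
    SlidePyramid,
    TissueMask,
)

# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class TrainConfig:
    base_learning_rate: float = 1e-6
    adam_epsilon: float = 1e-6
    weight_decay: float = 0.01
    positive_class_weight: float = 5.0
    tile_size_px: int = 512
    patience: int = 5
    max_epochs: int = 50
    seed: int = 0
    channel_widths: tuple[int, int] = (8, 16)   # encoder width, bottleneck width
    batch_size: int = 16

    def validate(self) -> None:
        if min(self.base_learning_rate, self.adam_epsilon,
               self.weight_decay, self.positive_class_weight) <= 0:
            raise InvalidSpecError("rates and weights must be positive")
        if self.tile_size_px % 2 != 0:
            raise InvalidSpecError("tile_size_px must be a multiple of the pool factor (2)")
        if self.max_epochs < 0 or self.patience < 0:
            raise InvalidSpecError("epoch counts must be non-negative")


#: Desk-scale override used by the package's own experiments: small tiles
#: at mask resolution and a learning rate suited to a from-scratch net.
DESK_TRAIN_CONFIG = TrainConfig(base_learning_rate=6e-3, tile_size_px=64,
                                patience=12, max_epochs=60, batch_size=16)

#: Scale of the optical-density-style input encoding.  Raw reflectance
#: differences between faintly stained tissue and background are a few
#: units out of 255; encoding pixels as (255 - v) / 64 amplifies
#: absorbance contrast so the first conv layer sees O(1) signal.
INPUT_OD_SCALE = 64.0


def encode_input(rgb: np.ndarray) -> np.ndarray:
    """Map uint8 RGB to the network's absorbance-like input encoding."""
    return (255.0 - np.asarray(rgb, np.float32)) / INPUT_OD_SCALE


@dataclass(frozen=True)
class AugmentationPolicy:
    flips: bool = True
    rotations_90: bool = True
    color_jitter_strength: float = 0.1

    def validate(self) -> None:
        if not 0.0 <= self.color_jitter_strength <= 1.0:
            raise InvalidSpecError("color_jitter_strength must be in [0, 1]")


@dataclass
class ModelCheckpoint:
    """Weights plus the config snapshot and validation score at save time."""

    weights: dict[str, np.ndarray]
    config: TrainConfig
    val_f1: float
    epoch: int
    history: list[tuple[int, float, float]] = field(default_factory=list)  # (epoch, loss, val_f1)


# ---------------------------------------------------------------------------
# Mirror padding


def padded_extent(dim: int, tile: int, stride: int) -> int:
    """Smallest tile + k*stride (k >= 0) that is >= dim."""
    if dim <= tile:
        return tile
    k = int(np.ceil((dim - tile) / stride))
    return tile + k * stride


def mirror_pad(
    raster: np.ndarray, tile_size: int, stride: int | None = None
) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflect-pad so a whole number of tiles (at ``stride``) fits.

    Padding is split as evenly as possible between opposite edges with
    the extra pixel going to bottom/right; returns the padded raster and
    the (top, left) offset of the original content.
    """
    if raster.size == 0:
        raise InvalidSpecError("cannot pad an empty raster")
    if stride is None:
        stride = tile_size
    h, w = raster.shape[:2]
    ph = padded_extent(h, tile_size, stride) - h
    pw = padded_extent(w, tile_size, stride) - w
    top, left = ph // 2, pw // 2
    pad = [(top, ph - top), (left, pw - left)] + [(0, 0)] * (raster.ndim - 2)
    return np.pad(raster, pad, mode="symmetric"), (top, left)


# ---------------------------------------------------------------------------
# Conv-net primitives (NCHW float32, zero-padded "same" 3x3 convs)


def _conv3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    n, ci, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.broadcast_to(b.reshape(1, -1, 1, 1), (n, W.shape[0], h, w)).copy()
    for ky in range(3):
        for kx in range(3):
            out += np.einsum("oi,nihw->nohw", W[:, :, ky, kx],
                             xp[:, :, ky:ky + h, kx:kx + w], optimize=True)
    return out


def _conv3_backward(x: np.ndarray, W: np.ndarray, dout: np.ndarray):
    n, ci, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for ky in range(3):
        for kx in range(3):
            patch = xp[:, :, ky:ky + h, kx:kx + w]
            dW[:, :, ky, kx] = np.einsum("nohw,nihw->oi", dout, patch, optimize=True)
            dxp[:, :, ky:ky + h, kx:kx + w] += np.einsum(
                "oi,nohw->nihw", W[:, :, ky, kx], dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dW, db


def _conv1_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.einsum("oi,nihw->nohw", W, x, optimize=True) + b.reshape(1, -1, 1, 1)


def _conv1_backward(x: np.ndarray, W: np.ndarray, dout: np.ndarray):
    dW = np.einsum("nohw,nihw->oi", dout, x, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dx = np.einsum("oi,nohw->nihw", W, dout, optimize=True)
    return dx, dW, db


def _pool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _pool2_backward(dout: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) * 0.25


def _up2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _up2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def init_weights(config: TrainConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-initialized weights for the one-level U-shaped net."""
    c, cb = config.channel_widths

    def he(co, ci, k):
        fan_in = ci * k * k
        shape = (co, ci, k, k) if k > 1 else (co, ci)
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)

    return {
        "W1": he(c, 3, 3), "b1": np.zeros(c, np.float32),
        "W2": he(c, c, 3), "b2": np.zeros(c, np.float32),
        "W3": he(cb, c, 3), "b3": np.zeros(cb, np.float32),
        "W4": he(c, c + cb, 3), "b4": np.zeros(c, np.float32),
        "W5": he(1, c, 1), "b5": np.zeros(1, np.float32),
    }


def forward(weights: dict[str, np.ndarray], x: np.ndarray, want_cache: bool = False):
    """Logits of shape (N, H, W) for encoded input (N, 3, H, W)."""
    a1 = np.maximum(_conv3_forward(x, weights["W1"], weights["b1"]), 0)
    a2 = np.maximum(_conv3_forward(a1, weights["W2"], weights["b2"]), 0)
    p = _pool2(a2)
    a3 = np.maximum(_conv3_forward(p, weights["W3"], weights["b3"]), 0)
    u = _up2(a3)
    cat = np.concatenate([a2, u], axis=1)
    a4 = np.maximum(_conv3_forward(cat, weights["W4"], weights["b4"]), 0)
    z = _conv1_forward(a4, weights["W5"], weights["b5"])[:, 0]
    if not want_cache:
        return z
    return z, (x, a1, a2, p, a3, cat, a4)


def backward(weights, cache, dz: np.ndarray) -> dict[str, np.ndarray]:
    x, a1, a2, p, a3, cat, a4 = cache
    c2 = a2.shape[1]
    grads: dict[str, np.ndarray] = {}
    da4, grads["W5"], grads["b5"] = _conv1_backward(a4, weights["W5"], dz[:, None])
    da4 *= a4 > 0
    dcat, grads["W4"], grads["b4"] = _conv3_backward(cat, weights["W4"], da4)
    da2 = dcat[:, :c2]
    du = dcat[:, c2:]
    da3 = _up2_backward(du)
    da3 *= a3 > 0
    dp, grads["W3"], grads["b3"] = _conv3_backward(p, weights["W3"], da3)
    da2 = da2 + _pool2_backward(dp)
    da2 *= a2 > 0
    da1, grads["W2"], grads["b2"] = _conv3_backward(a1, weights["W2"], da2)
    da1 *= a1 > 0
    _, grads["W1"], grads["b1"] = _conv3_backward(x, weights["W1"], da1)
    return grads


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce(z: np.ndarray, y: np.ndarray, pos_weight: float):
    """Mean weighted BCE-with-logits and its gradient wrt the logits."""
    sp = np.logaddexp(0.0, z)          # softplus(z)
    spm = sp - z                        # softplus(-z)
    loss = float(np.mean(pos_weight * y * spm + (1.0 - y) * sp))
    s = _sigmoid(z)
    dz = ((1.0 - y) * s - pos_weight * y * (1.0 - s)) / z.size
    return loss, dz.astype(np.float32)


class AdamW:
    """Decoupled-weight-decay Adam on a dict of parameter arrays."""

    def __init__(self, weights, lr, eps, weight_decay, betas=(0.9, 0.999)):
        self.lr, self.eps, self.wd = lr, eps, weight_decay
        self.b1, self.b2 = betas
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}

    def step(self, weights, grads) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            weights[k] -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * weights[k])


# ---------------------------------------------------------------------------
# Training


def pixel_f1(prob: np.ndarray, label: np.ndarray, threshold: float = 0.5) -> float:
    """F1 over the global pixel pool; 1.0 when both prediction and label are empty."""
    pred = prob > threshold
    label = label.astype(bool)
    tp = int(np.sum(pred & label))
    fp = int(np.sum(pred & ~label))
    fn = int(np.sum(~pred & label))
    denom = 2 * tp + fp + fn
    return 1.0 if denom == 0 else 2 * tp / denom


def _to_nchw(tiles: Sequence[tuple[np.ndarray, np.ndarray]]):
    imgs = np.stack([encode_input(t[0]) for t in tiles]).transpose(0, 3, 1, 2)
    labels = np.stack([np.asarray(t[1], np.float32) for t in tiles])
    return np.ascontiguousarray(imgs), labels


def _augment(imgs, labels, augs: AugmentationPolicy, rng: np.random.Generator):
    if augs.flips and rng.random() < 0.5:
        imgs, labels = imgs[..., ::-1], labels[..., ::-1]
    if augs.flips and rng.random() < 0.5:
        imgs, labels = imgs[:, :, ::-1], labels[:, ::-1]
    if augs.rotations_90:
        k = int(rng.integers(0, 4))
        if k:
            imgs = np.rot90(imgs, k, axes=(2, 3))
            labels = np.rot90(labels, k, axes=(1, 2))
    if augs.color_jitter_strength > 0:
        s = augs.color_jitter_strength
        gain = 1.0 + rng.uniform(-s, s, (imgs.shape[0], 3, 1, 1))
        bias = rng.uniform(-s, s, (imgs.shape[0], 3, 1, 1)) * 0.2
        imgs = np.clip(imgs * gain + bias, 0.0, 255.0 / INPUT_OD_SCALE)
    return np.ascontiguousarray(imgs, np.float32), np.ascontiguousarray(labels, np.float32)


def _val_f1(weights, imgs, labels, batch: int) -> float:
    probs = []
    for i in range(0, imgs.shape[0], batch):
        probs.append(_sigmoid(forward(weights, imgs[i:i + batch])))
    return pixel_f1(np.concatenate(probs), labels)


def train(
    train_tiles: Sequence[tuple[np.ndarray, np.ndarray]],
    val_tiles: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    augs: AugmentationPolicy | None = None,
) -> ModelCheckpoint:
    """Fit the segmenter; checkpoint the epoch with the best validation F1.

    Tiles are ``(HxWx3 uint8 image, HxW binary label)`` pairs.  Stops
    early after ``config.patience`` epochs without improvement;
    ``max_epochs=0`` returns the initial (untrained) checkpoint with its
    validation F1 recorded.
    """
    config.validate()
    if augs is None:
        augs = AugmentationPolicy()
    augs.validate()
    if len(train_tiles) == 0:
        raise InvalidSpecError("training set is empty")
    if len(val_tiles) == 0:
        raise InvalidSpecError("validation set is empty")

    rng = np.random.default_rng(config.seed)
    weights = init_weights(config, rng)
    opt = AdamW(weights, config.base_learning_rate, config.adam_epsilon, config.weight_decay)

    x_tr, y_tr = _to_nchw(train_tiles)
    x_va, y_va = _to_nchw(val_tiles)

    best = ModelCheckpoint({k: v.copy() for k, v in weights.items()}, config,
                           _val_f1(weights, x_va, y_va, config.batch_size), 0)
    history: list[tuple[int, float, float]] = []
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(x_tr.shape[0])
        losses = []
        for i in range(0, order.size, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = _augment(x_tr[idx], y_tr[idx], augs, rng)
            z, cache = forward(weights, xb, want_cache=True)
            loss, dz = weighted_bce(z, yb, config.positive_class_weight)
            grads = backward(weights, cache, dz)
            opt.step(weights, grads)
            losses.append(loss)
        f1 = _val_f1(weights, x_va, y_va, config.batch_size)
        history.append((epoch, float(np.mean(losses)), f1))
        if f1 > best.val_f1:
            best = ModelCheckpoint({k: v.copy() for k, v in weights.items()},
                                   config, f1, epoch)
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    best.history = history
    return best


# ---------------------------------------------------------------------------
# Overlap-discard inference


def overlap_discard_apply(
    raster: np.ndarray,
    fn: Callable[[np.ndarray], np.ndarray],
    tile_size: int,
    overlap: int,
) -> np.ndarray:
    """Apply a tile->tile function over a 2D grid, keeping tile centers.

    ``raster`` dims must already equal ``tile + k*stride`` with stride =
    ``tile - 2*overlap``.  Each output pixel is written exactly once:
    interior tiles contribute their central region, image-border tiles
    additionally keep their outer margins.
    """
    stride = tile_size - 2 * overlap
    if stride <= 0:
        raise InvalidSpecError("overlap must be < tile_size / 2")
    h, w = raster.shape[:2]
    if (h - tile_size) % stride or (w - tile_size) % stride:
        raise InvalidSpecError("raster dims must be tile + k*stride (mirror_pad first)")
    nr = (h - tile_size) // stride + 1
    nc = (w - tile_size) // stride + 1
    out = None
    for r in range(nr):
        y0 = r * stride
        ylo = 0 if r == 0 else overlap
        yhi = tile_size if r == nr - 1 else tile_size - overlap
        for c in range(nc):
            x0 = c * stride
            xlo = 0 if c == 0 else overlap
            xhi = tile_size if c == nc - 1 else tile_size - overlap
            pred = fn(raster[y0:y0 + tile_size, x0:x0 + tile_size])
            if out is None:
                out = np.zeros((h, w) + pred.shape[2:], dtype=pred.dtype)
            out[y0 + ylo:y0 + yhi, x0 + xlo:x0 + xhi] = pred[ylo:yhi, xlo:xhi]
    return out


def coverage_map(dims: tuple[int, int], tile_size: int, overlap: int) -> np.ndarray:
    """Count of writes per pixel under overlap-discard assembly."""
    counts = np.zeros(dims, dtype=np.int32)
    stride = tile_size - 2 * overlap
    if stride <= 0:
        raise InvalidSpecError("overlap must be < tile_size / 2")
    h, w = dims
    nr = (h - tile_size) // stride + 1
    nc = (w - tile_size) // stride + 1
    for r in range(nr):
        y0 = r * stride
        ylo = 0 if r == 0 else overlap
        yhi = tile_size if r == nr - 1 else tile_size - overlap
        for c in range(nc):
            x0 = c * stride
            xlo = 0 if c == 0 else overlap
            xhi = tile_size if c == nc - 1 else tile_size - overlap
            counts[y0 + ylo:y0 + yhi, x0 + xlo:x0 + xhi] += 1
    return counts


def predict_mask(
    slide: SlidePyramid,
    checkpoint: ModelCheckpoint,
    overlap: int | None = None,
    threshold: float = 0.5,
) -> TissueMask:
    """Tissue mask at 8.0 µm/px via mirror-pad + overlap-discard tiling.

    The default overlap is a quarter of the tile size (128 px for
    512-px tiles), so the inference stride is half a tile.
    """
    tile = checkpoint.config.tile_size_px
    if overlap is None:
        overlap = tile // 4
    stride = tile - 2 * overlap
    raster = slide.raster_at(MASK_MPP)
    h, w = raster.shape[:2]
    padded, (top, left) = mirror_pad(raster, tile, stride)

    def tile_prob(tile_rgb: np.ndarray) -> np.ndarray:
        x = encode_input(tile_rgb).transpose(2, 0, 1)[None]
        return _sigmoid(forward(checkpoint.weights, x))[0]

    prob = overlap_discard_apply(padded, tile_prob, tile, overlap)
    prob = prob[top:top + h, left:left + w]
    return TissueMask(prob > threshold, MASK_MPP, "learned", slide.slide_id)


# ---------------------------------------------------------------------------
# Model selection


def select_best_model(
    candidates: Sequence[tuple[float, float]], precision_floor: float = 0.90
) -> int:
    """Best-sensitivity candidate among those clearing the precision floor.

    Ties on sensitivity break to higher precision, then lower index.
    """
    if len(candidates) == 0:
        raise InvalidSpecError("candidate list is empty")
    qualified = [(sens, prec, i) for i, (sens, prec) in enumerate(candidates)
                 if prec >= precision_floor]
    if not qualified:
        raise NoQualifyingModelError(
            f"no candidate reaches precision >= {precision_floor}")
    qualified.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return qualified[0][2]


# ---------------------------------------------------------------------------
# Tile preparation from slides


def make_training_tiles(
    slides: Sequence[tuple[SlidePyramid, "object"]], tile_size: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cut (image, truth-label) tile pairs from slides at mask resolution.

    Mirror-pads image and label identically, then tiles without overlap
    — the training-time convention.
    """
    tiles = []
    for pyramid, truth in slides:
        raster = pyramid.raster_at(MASK_MPP)
        label = truth.tissue_mask.astype(np.uint8)
        rp, _ = mirror_pad(raster, tile_size)
        lp, _ = mirror_pad(label, tile_size)
        for y0 in range(0, rp.shape[0], tile_size):
            for x0 in range(0, rp.shape[1], tile_size):
                tiles.append((rp[y0:y0 + tile_size, x0:x0 + tile_size],
                              lp[y0:y0 + tile_size, x0:x0 + tile_size].astype(bool)))
    return tiles
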