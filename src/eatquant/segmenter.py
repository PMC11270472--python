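"""Per-slice EAT segmentation: a UNet-style encoder-decoder.

The network predicts, for every pixel of a (resized) axial slice, the
posterior probability that it belongs to epicardial fat.  Training minimizes
the sparse categorical cross-entropy

    E(theta) = -(1/N) * sum_n y_n log( p_n(x_n, theta) )

averaged over samples and pixels, where ``p_n`` is the posterior of the true
class from a two-channel per-pixel softmax head.  The recipe follows the
full-scale protocol: batch size 64, Adam at an initial learning rate of 1e-4
decaying exponentially at rate 0.05 per epoch after the first 5, batch
normalization after convolutions, dropout in the bottleneck, and rotation /
cropping / intensity-normalization augmentation.

Predicted probability maps live on the model grid (224 x 224 at full scale)
and are upscaled to the native CT grid by area (bilinear-for-enlargement)
interpolation *before* binarization, so mask boundaries stay smooth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import nn
from .handles import ModelHandle
from .image_io import BinaryMask, CTSeries
from .preprocess import preprocess_slice, random_crop_resize, resize_image

EPS_CLIP = 1e-7


class SegmenterError(ValueError):
    pass


@dataclass
class ProbMask:
    """Per-pixel EAT posterior on the model grid."""

    grid: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=np.float32)
        if g.min() < 0 or g.max() > 1:
            raise SegmenterError("posterior values must lie in [0, 1]")
        self.grid = g


def sparse_ce_loss(probs: np.ndarray, masks: np.ndarray) -> float:
    """Mean per-pixel cross-entropy of the true class.

    ``probs`` holds class-1 posteriors (any shape); ``masks`` the 0/1 truth of
    the same shape.  Posteriors are epsilon-clipped away from {0, 1}.
    """
    probs = np.asarray(probs, dtype=np.float64)
    masks = np.asarray(masks)
    if probs.shape != masks.shape:
        raise SegmenterError(f"probs shape {probs.shape} != masks shape {masks.shape}")
    p = np.clip(probs, EPS_CLIP, 1.0 - EPS_CLIP)
    ll = np.where(masks == 1, np.log(p), np.log1p(-p))
    return float(-ll.mean())


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

@dataclass
class SegmenterConfig:
    """Training recipe; defaults are the full-scale protocol."""

    epochs: int = 60
    batch_size: int = 64
    lr: float = 1e-4
    lr_decay_rate: float = 0.05  # exponential decay per epoch ...
    lr_decay_after: int = 5  # ... after this many constant epochs
    input_size: int = 224
    base_filters: int = 16
    depth: int = 2
    dropout: float = 0.5
    rotation_deg: float = 15.0
    crop_min_frac: float = 0.9
    augment: bool = True
    hu_clip: tuple = (-1000.0, 1000.0)
    threshold: float = 0.5
    seed: int = 0


def lr_schedule(cfg: SegmenterConfig, epoch: int) -> float:
    """Learning rate for 1-based ``epoch``: constant, then exponential decay."""
    if epoch <= cfg.lr_decay_after:
        return cfg.lr
    return cfg.lr * math.exp(-cfg.lr_decay_rate * (epoch - cfg.lr_decay_after))


class SmallUNet:
    """Encoder-decoder with skip connections and a 2-class softmax head."""

    def __init__(self, config: dict | SegmenterConfig, rng: np.random.Generator):
        cfg = asdict(config) if isinstance(config, SegmenterConfig) else config
        base, depth = cfg["base_filters"], cfg["depth"]
        self.depth = depth
        self.enc = []
        c = 1
        for d in range(depth):
            f = base * 2 ** d
            self.enc.append((nn.ConvBNReLU(c, f, rng), nn.ConvBNReLU(f, f, rng), nn.MaxPool2()))
            c = f
        fb = base * 2 ** depth
        self.mid1 = nn.ConvBNReLU(c, fb, rng)
        self.mid2 = nn.ConvBNReLU(fb, fb, rng)
        self.drop = nn.Dropout(cfg["dropout"], np.random.default_rng([cfg["seed"], 777]))
        self.dec = []
        c = fb
        for d in reversed(range(depth)):
            f = base * 2 ** d
            self.dec.append(
                (nn.Upsample2(), nn.ConvBNReLU(c, f, rng), nn.ConvBNReLU(2 * f, f, rng),
                 nn.ConvBNReLU(f, f, rng))
            )
            c = f
        self.head = nn.Conv2D(base, 2, 1, rng)
        self.layers = (
            [l for trio in self.enc for l in trio]
            + [self.mid1, self.mid2, self.drop]
            + [l for quad in self.dec for l in quad]
            + [self.head]
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        skips = []
        h = x
        for cbr1, cbr2, pool in self.enc:
            h = cbr2.forward(cbr1.forward(h, train), train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.drop.forward(self.mid2.forward(self.mid1.forward(h, train), train), train)
        for (up, red, cbr1, cbr2), skip in zip(self.dec, reversed(skips)):
            h = red.forward(up.forward(h, train), train)
            h = np.concatenate([skip, h], axis=1)
            h = cbr2.forward(cbr1.forward(h, train), train)
        return self.head.forward(h, train)  # logits (N, 2, H, W)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = {}
        # forward applied self.dec in list order (deepest -> shallowest), so
        # backward walks the list in reverse
        for i in range(len(self.dec) - 1, -1, -1):
            up, red, cbr1, cbr2 = self.dec[i]
            lvl = self.depth - 1 - i  # encoder level whose skip was concatenated
            f = red.conv.W.shape[0]
            d = cbr1.backward(cbr2.backward(d))
            dskips[lvl] = d[:, :f]
            d = up.backward(red.backward(d[:, f:]))
        d = self.mid1.backward(self.mid2.backward(self.drop.backward(d)))
        for lvl in range(self.depth - 1, -1, -1):
            cbr1, cbr2, pool = self.enc[lvl]
            d = pool.backward(d)
            d = d + dskips[lvl]
            d = cbr1.backward(cbr2.backward(d))


def build_segmenter(config: dict, seed: int) -> SmallUNet:
    return SmallUNet(config, np.random.default_rng([seed, 303]))


def _softmax2(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def train_segmenter(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    config: SegmenterConfig | None = None,
) -> ModelHandle:
    """Train the UNet on (HU slice, binary mask) pairs.

    Intended for EAT-containing slices only (the classifier screens the rest).
    Deterministic under a fixed seed; per-epoch mean loss recorded on the
    returned handle.
    """
    cfg = config or SegmenterConfig()
    if len(images) == 0:
        raise SegmenterError("empty training set")
    if len(images) != len(masks):
        raise SegmenterError("images and masks length mismatch")

    rng = np.random.default_rng([cfg.seed, 303])
    aug_rng = np.random.default_rng([cfg.seed, 304])
    model = SmallUNet(asdict(cfg), rng)
    X = np.stack([preprocess_slice(im, cfg.input_size, cfg.hu_clip) for im in images])[:, None]
    Y = np.stack(
        [(resize_image(np.asarray(m, dtype=np.float32), cfg.input_size, order=0) > 0.5) for m in masks]
    ).astype(np.int8)

    leaves = nn.all_leaf_layers(model.layers)
    params = [p for l in leaves for p in l.params()]
    grads = [g for l in leaves for g in l.grads()]
    opt = nn.Adam(params, grads, lr=cfg.lr)

    history = []
    n = len(X)
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = lr_schedule(cfg, epoch)
        order = np.random.default_rng([cfg.seed, 400 + epoch]).permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = X[idx].copy(), Y[idx].copy()
            if cfg.augment:
                for j in range(len(xb)):
                    angle = float(aug_rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
                    xb[j, 0] = ndimage.rotate(
                        xb[j, 0], angle, reshape=False, order=1, mode="constant", cval=0.0
                    )
                    yb[j] = ndimage.rotate(
                        yb[j], angle, reshape=False, order=0, mode="constant", cval=0
                    )
                    if aug_rng.random() < 0.5:
                        xb[j, 0], yb[j] = random_crop_resize(
                            xb[j, 0], aug_rng, cfg.crop_min_frac, mask=yb[j]
                        )
            logits = model.forward(xb, train=True)
            p = _softmax2(logits)
            losses.append(sparse_ce_loss(p[:, 1], yb))
            onehot = np.stack([1 - yb, yb], axis=1)
            npix = p[0, 0].size
            dlogits = (p - onehot) / (len(xb) * npix)
            model.backward(dlogits.astype(np.float32))
            opt.step()
        history.append(float(np.mean(losses)))

    return ModelHandle(
        kind="segmenter", model=model, config=asdict(cfg), seed=cfg.seed,
        history=history, trained=True,
    )


def segment_slices(handle: ModelHandle, series: CTSeries | Sequence[np.ndarray]) -> list[ProbMask]:
    """Per-slice EAT posterior maps on the model grid, in [0, 1]."""
    handle.require_trained()
    cfg = handle.config
    pixels = [s.pixels for s in series] if isinstance(series, CTSeries) else list(series)
    X = np.stack(
        [preprocess_slice(im, cfg["input_size"], tuple(cfg["hu_clip"])) for im in pixels]
    )[:, None]
    out = []
    for start in range(0, len(X), 32):
        logits = handle.model.forward(X[start : start + 32], train=False)
        probs = _softmax2(logits)[:, 1]
        out.extend(ProbMask(grid=g) for g in probs)
    return out


def upscale_mask(
    grid: np.ndarray,
    target_size: int = 512,
    threshold: float = 0.5,
    spacing: tuple[float, float] = (1.0, 1.0),
    binarize_first: bool = False,
) -> BinaryMask:
    """Upscale a (probability or binary) mask to the native CT grid.

    The field is resampled by pixel-area/bilinear interpolation and *then*
    binarized at ``threshold`` (default 0.5); ``binarize_first=True`` gives the
    blockier binary-first variant for ablation.  Shrinking is refused.
    """
    g = np.asarray(grid, dtype=np.float64)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise SegmenterError(f"mask must be square 2D, got {g.shape}")
    if target_size < g.shape[0]:
        raise SegmenterError(f"refusing to shrink {g.shape[0]} -> {target_size}")
    if binarize_first:
        g = (g >= threshold).astype(np.float64)
    up = resize_image(g.astype(np.float32), target_size, order=1)
    return BinaryMask(grid=(up >= threshold).astype(np.uint8), sx=spacing[0], sy=spacing[1])
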