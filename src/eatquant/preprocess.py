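"""Shared image preprocessing and in-training augmentation.

Both models see the same deterministic preprocessing: HU values clipped to a
wide window, min-max normalized per slice to [0, 1], and resized to the model
input grid.  The preprocessing parameters travel with the trained model so
inference always matches training.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.transform import resize


def normalize_hu(pixels: np.ndarray, hu_clip: tuple[float, float] = (-1000.0, 1000.0)) -> np.ndarray:
    """Clip HU to ``hu_clip`` and min-max scale the slice to [0, 1]."""
    x = np.clip(np.asarray(pixels, dtype=np.float32), hu_clip[0], hu_clip[1])
    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        x = (x - lo) / (hi - lo)
    else:
        x = np.zeros_like(x)
    return x


def resize_image(img: np.ndarray, size: int, order: int = 1) -> np.ndarray:
    if img.shape == (size, size):
        return np.asarray(img, dtype=np.float32)
    out = resize(img.astype(np.float64), (size, size), order=order, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return out.astype(np.float32)


def preprocess_slice(pixels: np.ndarray, size: int,
                     hu_clip: tuple[float, float] = (-1000.0, 1000.0)) -> np.ndarray:
    return resize_image(normalize_hu(pixels, hu_clip), size)


def random_rotation(img: np.ndarray, rng: np.random.Generator,
                    max_deg: float = 15.0, fill: float = 0.0) -> np.ndarray:
    """Rotate by an angle drawn uniformly in [-max_deg, +max_deg]."""
    angle = float(rng.uniform(-max_deg, max_deg))
    return ndimage.rotate(img, angle, reshape=False, order=1, mode="constant",
                          cval=fill).astype(np.float32)


def random_crop_resize(img: np.ndarray, rng: np.random.Generator,
                       min_frac: float = 0.9,
                       mask: np.ndarray | None = None):
    """Random crop to ``min_frac``–100% of the field, resized back.

    If ``mask`` is given it receives the identical crop (nearest-neighbor
    resize) so image/mask stay aligned.
    """
    h, w = img.shape
    frac = float(rng.uniform(min_frac, 1.0))
    ch, cw = max(2, int(round(h * frac))), max(2, int(round(w * frac)))
    y0 = int(rng.integers(0, h - ch + 1))
    x0 = int(rng.integers(0, w - cw + 1))
    out = resize_image(img[y0:y0 + ch, x0:x0 + cw], h)
    if mask is None:
        return out
    m = resize_image(mask[y0:y0 + ch, x0:x0 + cw].astype(np.float32), h, order=0)
    return out, (m > 0.5).astype(np.uint8)
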