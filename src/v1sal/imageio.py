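"""Grayscale image reading/writing (PNG/PGM/TIFF via Pillow)."""

from __future__ import annotations

import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image", "write_map16"]


def read_image(path) -> np.ndarray:
    """Load an image as float64 grayscale rescaled to [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("F"), dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi > 1.0:
        arr = arr / 255.0 if hi <= 255.0 else (arr - lo) / (hi - lo)
    return np.clip(arr, 0.0, 1.0)


def write_image(path, arr: np.ndarray) -> None:
    """Write a float array as 8-bit grayscale (clipped to [0, 1])."""
    a = np.clip(np.asarray(arr, dtype=np.float64), 0.0, 1.0)
    Image.fromarray((a * 255).round().astype(np.uint8), mode="L").save(path)


def write_map16(path, arr: np.ndarray) -> None:
    """Write a nonnegative map as max-normalized 16-bit PNG."""
    a = np.asarray(arr, dtype=np.float64)
    mx = a.max()
    a = a / mx if mx > 0 else a
    Image.fromarray((a * 65535).round().astype(np.uint16)).save(path)
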