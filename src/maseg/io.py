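"""Reading and writing images and masks.

Input frames may be 8- or 16-bit grayscale or RGB PNG/TIFF. In FFA exports
the three RGB channels carry identical data, so channel 0 is taken; if the
channels differ beyond a tolerance the file is probably not an FFA frame
and a warning is raised. 16-bit data are rescaled onto [0, 255]. All
processing is float; quantization (round half away from zero) happens only
when an 8-bit file is written.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_image", "write_image_u8", "write_mask", "read_mask"]


def read_image(path, channel_tolerance: float = 1.0) -> np.ndarray:
    """Load a frame as a float64 grayscale array scaled to [0, 255]."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"empty image: {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        spread = np.abs(
            arr[:, :, :3].astype(float).max(axis=2)
            - arr[:, :, :3].astype(float).min(axis=2)
        )
        if spread.max() > channel_tolerance:
            warnings.warn(
                f"{path.name}: RGB channels differ (max spread "
                f"{spread.max():.1f}); not a typical FFA export — using channel 0",
                stacklevel=2,
            )
        arr = arr[:, :, 0]
    arr = arr.astype(float)
    if arr.max() > 255.0:  # 16-bit source
        arr *= 255.0 / 65535.0
    return arr


def _quantize_u8(img: np.ndarray) -> np.ndarray:
    """Round half away from zero and clip to [0, 255]."""
    q = np.floor(np.abs(img) + 0.5) * np.sign(img)
    return np.clip(q, 0, 255).astype(np.uint8)


def write_image_u8(path, img: np.ndarray) -> None:
    iio.imwrite(Path(path), _quantize_u8(np.asarray(img, dtype=float)))


def write_mask(path, mask: np.ndarray) -> None:
    """Binary mask as 8-bit PNG with foreground 255."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Load a mask file: any nonzero pixel is foreground."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 0
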