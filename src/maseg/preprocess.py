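"""Image enhancement for fluorescein fundus angiography (FFA) frames.

FFA frames are low-contrast and noisy; microaneurysms (MAs) are small bright
dots a few pixels across. The enhancement chain is

    top-hat (disk radius 45)  ->  gray stretch to [0, 255]  ->  Gaussian smooth

The top-hat transform (image minus its grayscale opening) removes smooth
background and uneven illumination while keeping bright structures narrower
than the structuring element; gray stretching maps the residual onto the full
8-bit range; a small Gaussian suppresses residual noise without destroying
3-px lesions.

All arithmetic is float64; quantization to 8 bits happens only on file
output. Borders are handled by edge replication everywhere so no artificial
dark/bright rims appear at the frame edge (such rims would turn into false
MA candidates downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "PreprocessConfig",
    "disk_footprint",
    "erode",
    "dilate",
    "gray_open",
    "tophat",
    "gray_stretch",
    "gaussian_kernel",
    "gaussian_smooth",
    "preprocess_image",
]


@dataclass
class PreprocessConfig:
    """Parameters of the enhancement chain.

    tophat_radius : radius in px of the flat disk structuring element. The
        default 45 is much larger than any MA, so lesions survive the
        opening and the top-hat residual keeps them intact.
    gmin, gmax : output bounds of the gray stretch (8-bit convention).
    gaussian_sigma : standard deviation in px of the smoothing kernel;
        small enough to preserve 3-px dots.
    gaussian_truncate_radius : kernel half-width in px; ``None`` means
        ceil(3 * sigma).
    """

    tophat_radius: int = 45
    gmin: float = 0.0
    gmax: float = 255.0
    gaussian_sigma: float = 1.0
    gaussian_truncate_radius: int | None = None


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a nonempty 2-D grayscale image")
    return img


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean flat disk: (u, v) belongs iff u^2 + v^2 <= radius^2."""
    if radius < 1:
        raise ValueError("structuring-element radius must be >= 1")
    r = int(radius)
    u, v = np.mgrid[-r : r + 1, -r : r + 1]
    return u * u + v * v <= r * r


def erode(img: np.ndarray, radius: int = 45) -> np.ndarray:
    """Grayscale erosion by a flat disk: per-pixel neighborhood minimum."""
    img = _check_image(img)
    return ndi.grey_erosion(img, footprint=disk_footprint(radius), mode="nearest")


def dilate(img: np.ndarray, radius: int = 45) -> np.ndarray:
    """Grayscale dilation by a flat disk: per-pixel neighborhood maximum."""
    img = _check_image(img)
    return ndi.grey_dilation(img, footprint=disk_footprint(radius), mode="nearest")


def gray_open(img: np.ndarray, radius: int = 45) -> np.ndarray:
    """Grayscale opening: erosion followed by dilation with the same disk."""
    img = _check_image(img)
    fp = disk_footprint(radius)
    return ndi.grey_dilation(
        ndi.grey_erosion(img, footprint=fp, mode="nearest"),
        footprint=fp,
        mode="nearest",
    )


def tophat(img: np.ndarray, radius: int = 45) -> np.ndarray:
    """White top-hat: image minus its opening.

    Nonnegative everywhere; bright structures smaller than the disk are
    preserved, smooth background is flattened to ~0.
    """
    img = _check_image(img)
    return img - gray_open(img, radius)


def gray_stretch(
    img: np.ndarray, gmin: float = 0.0, gmax: float = 255.0
) -> np.ndarray:
    """Affine contrast stretch mapping [min(img), max(img)] onto [gmin, gmax].

    A constant image has no dynamic range to stretch; it maps to all-gmin
    with a warning (so batch runs survive blank frames).
    """
    img = _check_image(img)
    if gmax <= gmin:
        raise ValueError("gmax must exceed gmin")
    imin = float(img.min())
    imax = float(img.max())
    if imax == imin:
        warnings.warn(
            "gray_stretch: constant image, returning all-gmin", stacklevel=2
        )
        return np.full_like(img, gmin)
    # normalize first so the extremes map to exactly gmin and gmax
    return (img - imin) / (imax - imin) * (gmax - gmin) + gmin


def gaussian_kernel(sigma: float, truncate_radius: int | None = None) -> np.ndarray:
    """Discretized 2-D isotropic Gaussian, renormalized to sum exactly 1."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = int(np.ceil(3.0 * sigma)) if truncate_radius is None else int(truncate_radius)
    if r < 1:
        raise ValueError("truncation radius must be >= 1")
    x, y = np.mgrid[-r : r + 1, -r : r + 1]
    k = np.exp(-(x * x + y * y) / (2.0 * sigma * sigma))
    return k / k.sum()


def gaussian_smooth(
    img: np.ndarray, sigma: float = 1.0, truncate_radius: int | None = None
) -> np.ndarray:
    """Convolve with the renormalized Gaussian kernel (edge-replicated).

    Because the kernel sums to 1 a constant image is preserved exactly and
    the output never exceeds the input maximum.
    """
    img = _check_image(img)
    k = gaussian_kernel(sigma, truncate_radius)
    return ndi.correlate(img, k, mode="nearest")


def preprocess_image(
    raw: np.ndarray, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Full enhancement chain: top-hat -> gray stretch -> Gaussian smooth."""
    cfg = cfg or PreprocessConfig()
    raw = _check_image(raw)
    th = tophat(raw, cfg.tophat_radius)
    st = gray_stretch(th, cfg.gmin, cfg.gmax)
    return gaussian_smooth(st, cfg.gaussian_sigma, cfg.gaussian_truncate_radius)
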