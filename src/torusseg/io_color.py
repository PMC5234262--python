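"""Raster I/O and RGB-to-grayscale conversion.

The segmentation method operates on a single-channel *amplitude* image
``A(m, n)`` obtained from an RGB photograph by the CIE 1931 luminance
combination ``Y = 0.2126 R + 0.7152 G + 0.0722 B``.  Amplitudes are kept
real-valued (no 8-bit re-quantization) because every downstream transform
is continuous.

Conventions: arrays are ``(N, M)`` / ``(N, M, 3)`` with row index ``m``
counting vertical pixels (height ``N``) and column index ``n`` horizontal
pixels (width ``M``).  Binary masks are boolean arrays, written to disk as
8-bit PNGs with values {0, 255}.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio
from skimage.transform import resize

from .errors import ImageIOError, InvalidImageError

#: CIE 1931 luminance weights for (R, G, B); they sum to 1.
GRAY_WEIGHTS = (0.2126, 0.7152, 0.0722)


def rgb_to_gray(img: np.ndarray) -> np.ndarray:
    """Convert an ``(N, M, 3)`` RGB image to a real-valued amplitude image.

    Parameters
    ----------
    img : ndarray
        RGB pixels with channel values in [0, 255].

    Returns
    -------
    ndarray
        ``(N, M)`` float64 amplitudes in [0, 255], not rounded to integers.

    Raises
    ------
    InvalidImageError
        If the array is not three-channel or values fall outside [0, 255].
    """
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidImageError(
            f"expected an (N, M, 3) RGB array, got shape {arr.shape}"
        )
    arr = arr.astype(np.float64)
    if arr.min() < 0 or arr.max() > 255:
        raise InvalidImageError("RGB channel values must lie within [0, 255]")
    w = np.asarray(GRAY_WEIGHTS)
    return arr @ w


def load_image(path) -> np.ndarray:
    """Read a JPEG/PNG file as an ``(N, M, 3)`` uint8 RGB array.

    Grayscale files are replicated to three identical channels; an alpha
    channel, if present, is dropped.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various decoder errors
        raise ImageIOError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageIOError(
            f"unsupported image layout {arr.shape} in file {path!r}"
        )
    if arr.dtype != np.uint8:
        # 16-bit PNGs are rescaled onto the 8-bit working range.
        arr = (arr.astype(np.float64) / np.iinfo(arr.dtype).max * 255.0)
        arr = np.rint(arr).astype(np.uint8)
    return arr


def save_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit single-channel PNG with values {0, 255}."""
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise InvalidImageError("mask values must be strictly binary {0, 1}")
    out = (arr.astype(np.uint8)) * np.uint8(255)
    try:
        iio.imwrite(path, out, extension=".png")
    except Exception as exc:
        raise ImageIOError(f"cannot write mask to {path!r}: {exc}") from exc


def load_mask(path) -> np.ndarray:
    """Read a mask PNG back to a boolean array (any nonzero pixel is True)."""
    rgb = load_image(path)
    return rgb[..., 0] > 127


def downscale_max_side(gray: np.ndarray, max_side: int) -> np.ndarray:
    """Downscale so the longest side is ``max_side`` pixels, if it exceeds it.

    Anti-aliased (area-averaging) interpolation; images already within the
    bound are returned unchanged.  Upscaling is never performed.
    """
    n, m = gray.shape
    longest = max(n, m)
    if longest <= max_side:
        return gray
    scale = max_side / longest
    new_shape = (max(1, round(n * scale)), max(1, round(m * scale)))
    return resize(
        gray, new_shape, order=1, anti_aliasing=True, preserve_range=True
    )
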