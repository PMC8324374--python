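"""Raster image I/O and channel arithmetic for stained blood smears.

Images are plain :class:`numpy.ndarray` objects, following the scikit-image
convention: an RGB micrograph is ``(H, W, 3)`` ``uint8``, a grayscale image is
``(H, W)`` ``uint8`` and a binary mask is ``(H, W)`` ``bool``.  Arrays are
indexed ``[row, col]`` with the origin at the top-left.

The one domain-specific operation here is :func:`channel_difference`: after
Wright's staining, nuclei and platelets are blue-purple (blue channel well
above green) while the background and erythrocytes are near-neutral pink
(blue approximately equal to green), so the clamped ``B - G`` image isolates
nuclear material in a single gray channel.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = [
    "load_image",
    "save_image",
    "channel_difference",
    "histogram",
    "render_overlay",
    "color_space_size",
]


def color_space_size(bits_per_channel: int = 8, channels: int = 3) -> int:
    """Number of distinct colors an image can encode: (2^bits)^channels.

    For standard 8-bit RGB this is (2^8)^3 = 16 777 216.
    """
    return (2**bits_per_channel) ** channels


class UnsupportedImageError(ValueError):
    """Raised for images that are not plain 8-bit-per-channel RGB."""


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load an 8-bit RGB image (PNG/TIFF/BMP) as an ``(H, W, 3) uint8`` array.

    Alpha channels, palette images and bit depths other than 8 are rejected
    rather than silently converted.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    UnsupportedImageError
        If the file is not 8-bit RGB.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise UnsupportedImageError(
            f"expected 8-bit image, got dtype {arr.dtype} in {path}"
        )
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise UnsupportedImageError(
            f"expected an RGB image (H, W, 3), got shape {arr.shape} in {path}"
        )
    return arr


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an RGB image, grayscale image or binary mask losslessly.

    The file format follows the extension (PNG or TIFF).  Boolean masks are
    serialized as 0/255 single-channel images; reloading and thresholding at
    any level recovers the original mask.
    """
    arr = np.asarray(img)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if arr.dtype != np.uint8:
        arr = arr.astype(np.uint8)
    iio.imwrite(path, arr)


def channel_difference(img: np.ndarray) -> np.ndarray:
    """Clamped blue-minus-green difference image.

    Per pixel the output is ``clip(B - G, 0, 255)``.  Nucleus and platelet
    pixels (B > G under Wright's staining) map to high values; background and
    erythrocyte pixels map near zero.  The red channel never influences the
    result.
    """
    img = np.asarray(img)
    b = img[..., 2].astype(np.int16)
    g = img[..., 1].astype(np.int16)
    return np.clip(b - g, 0, 255).astype(np.uint8)


def histogram(gray: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram; ``counts[k]`` is the number of pixels
    with value ``k`` and the counts sum to the pixel count."""
    gray = np.asarray(gray)
    if gray.dtype != np.uint8:
        raise ValueError(f"expected uint8 grayscale image, got {gray.dtype}")
    return np.bincount(gray.ravel(), minlength=256)


def render_overlay(
    img: np.ndarray,
    mask: np.ndarray,
    stain_color: tuple[int, int, int] = (255, 0, 0),
) -> np.ndarray:
    """Stain the mask region onto a copy of the image.

    Pixels where ``mask`` is set are replaced by *stain_color*; all other
    pixels are bit-identical to the input.  This is the standard visual check
    for over-/under-segmentation: the stained binary result is superimposed
    on the original micrograph to inspect the nuclear boundary.
    """
    img = np.asarray(img)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {img.shape[:2]}"
        )
    out = img.copy()
    out[mask] = np.asarray(stain_color, dtype=np.uint8)
    return out
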