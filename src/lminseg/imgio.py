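"""Image and mask I/O.

Conventions used throughout the package:

* A *gray image* is a 2-D ``float64`` array with intensities in [0, 1],
  row-major, indexed ``(row, col)``, 0-based.
* A *binary mask* is a 2-D ``bool`` array of the same shape as its source
  image.
* A *tri-level mask* is the ground-truth convention for single-cell blood
  smears: a 2-D ``uint8`` array whose only values are 0 (background,
  including red blood cells), 128 (cytoplasm) and 255 (nucleus).

Grayscale conversion uses the ITU-R BT.601 luminance weights
(0.299, 0.587, 0.114).  Integer inputs are normalized by the dtype maximum
(255 for 8-bit, 65535 for 16-bit), never min–max stretched, so that the
per-image minimum and maximum keep their meaning for threshold estimation.
"""

from __future__ import annotations

import imageio.v3 as iio
import numpy as np

from .errors import DegenerateInputError, FormatError

__all__ = [
    "BT601_WEIGHTS",
    "TRILEVEL_CODES",
    "as_gray",
    "read_image",
    "read_trilevel_mask",
    "write_mask",
]

BT601_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: on-disk label codes: background, cytoplasm, nucleus
TRILEVEL_CODES = np.array([0, 128, 255], dtype=np.uint8)

#: a pixel farther than this from every tri-level code is a format error
_SNAP_TOLERANCE = 40


def as_gray(arr: np.ndarray) -> np.ndarray:
    """Convert an in-memory array (gray or RGB[A], any integer/float dtype)
    to a normalized [0, 1] float64 gray image."""
    arr = np.asarray(arr)
    if arr.size == 0:
        raise DegenerateInputError("zero-sized image")
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            arr = arr[..., :3] @ BT601_WEIGHTS
        else:
            arr = arr[..., 0]
    elif arr.ndim != 2:
        raise FormatError(f"expected a 2-D or 3-D image, got shape {arr.shape}")
    out = np.asarray(arr, dtype=np.float64)
    if out.max(initial=0.0) > 1.0:
        scale = 65535.0 if out.max() > 255.0 else 255.0
        out = out / scale
    return np.clip(out, 0.0, 1.0)


def _imread(path) -> np.ndarray:
    """Decode a raster file, normalizing decoder failures to OSError."""
    try:
        return iio.imread(path)
    except OSError:
        raise
    except Exception as exc:  # decoder plugins raise assorted types
        raise OSError(f"cannot decode image file {path}: {exc}") from exc


def read_image(path) -> np.ndarray:
    """Read a raster image (PNG/JPG/BMP/TIFF, gray or RGB) as a normalized
    gray image in [0, 1].

    Integer pixel values are divided by the dtype maximum inferred from the
    stored bit depth; RGB is collapsed with BT.601 luminance weights.

    Raises
    ------
    OSError
        If the file cannot be read or decoded.
    DegenerateInputError
        If the decoded image has no pixels.
    """
    raw = _imread(path)
    if raw.size == 0:
        raise DegenerateInputError(f"zero-sized image: {path}")
    if raw.ndim == 3 and raw.shape[2] >= 3:
        gray = raw[..., :3].astype(np.float64) @ BT601_WEIGHTS
    elif raw.ndim == 3:
        gray = raw[..., 0].astype(np.float64)
    elif raw.ndim == 2:
        gray = raw.astype(np.float64)
    else:
        raise FormatError(f"unsupported image shape {raw.shape} in {path}")
    if np.issubdtype(raw.dtype, np.integer):
        gray = gray / np.iinfo(raw.dtype).max
    elif gray.max(initial=0.0) > 1.0:
        gray = gray / gray.max()
    return np.clip(gray, 0.0, 1.0)


def read_trilevel_mask(path) -> np.ndarray:
    """Read a tri-level ground-truth mask (nucleus=255, cytoplasm=128,
    background=0), snapping compression noise to the nearest code.

    Raises
    ------
    FormatError
        If any pixel is more than 40 gray levels from every code, which
        indicates the file is not a tri-level mask.
    """
    raw = _imread(path)
    if raw.ndim == 3:
        raw = raw[..., 0]
    raw = raw.astype(np.int64)
    if raw.size == 0:
        raise DegenerateInputError(f"zero-sized mask: {path}")
    dist = np.abs(raw[..., None] - TRILEVEL_CODES.astype(np.int64))
    nearest = dist.argmin(axis=-1)
    mindist = dist.min(axis=-1)
    if (mindist > _SNAP_TOLERANCE).any():
        bad = np.unique(raw[mindist > _SNAP_TOLERANCE])
        raise FormatError(
            f"not a tri-level mask: values {bad.tolist()} are more than "
            f"{_SNAP_TOLERANCE} gray levels from every code in {{0,128,255}}"
        )
    return TRILEVEL_CODES[nearest]


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary or tri-level mask losslessly as PNG.

    Binary masks are stored as {0, 255}; tri-level masks keep their codes.
    Reading the file back reproduces the labels exactly.
    """
    mask = np.asarray(mask)
    if mask.dtype == bool:
        data = np.where(mask, 255, 0).astype(np.uint8)
    else:
        data = mask.astype(np.uint8)
        extra = np.setdiff1d(np.unique(data), TRILEVEL_CODES)
        if extra.size:
            raise FormatError(
                f"mask values {extra.tolist()} are neither binary nor tri-level codes"
            )
    kwargs = {} if str(path).lower().endswith(".png") else {"extension": ".png"}
    iio.imwrite(path, data, **kwargs)


def trilevel_to_binary(mask: np.ndarray, labels=(255,)) -> np.ndarray:
    """Extract a binary mask from a tri-level mask.

    ``labels=(255,)`` gives the nucleus; ``labels=(255, 128)`` gives the
    whole white blood cell (nucleus plus cytoplasm).
    """
    mask = np.asarray(mask)
    return np.isin(mask, np.asarray(labels))
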