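"""Whole-cell (WBC) segmentation by averaged multi-threshold reconstruction.

The cytoplasm of a white blood cell is textured, so a single threshold on
the raw image fragments it.  Instead, ``n`` floor-thresholded copies of
the image are averaged: each copy raises every pixel at or below its
threshold up to that threshold, so the average strongly compresses the
intensity variability inside the cell while the bright background and the
pale rims of red blood cells stay distinct.  The averaged image is then
binarized with Otsu's method (the cell is the dark class), cleaned
morphologically, and the connected component containing a seed pixel from
the segmented nucleus is extracted as the WBC.  The cytoplasm is the WBC
minus the nucleus.

The threshold family is

    T_wbc_i = (Max(A) + T_nc0) / 2 + er_i,   er_i = a_l + i * Δh,

with ``a_l = Min(A)``, ``a_u = Max(A)/3``, ``Δh = (a_u - a_l)/(n - 1)``
and ``i = 0 .. n-1``, so the step values run inclusively from ``a_l`` to
``a_u``.  Thresholds exceeding ``Max(A)`` are clipped: the corresponding
copies saturate harmlessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import (
    DegenerateInputError,
    EmptyMaskError,
    ParameterError,
    SeedNotOnForegroundError,
)
from .nucleus import NucleusParams, compute_initial_value, postprocess_mask

__all__ = [
    "WBCThresholdFamily",
    "generate_wbc_thresholds",
    "threshold_image",
    "average_reconstruction",
    "otsu_threshold",
    "select_seed_from_nucleus",
    "extract_wbc_by_seed",
    "compute_cytoplasm",
    "segment_wbc",
]


@dataclass(frozen=True)
class WBCThresholdFamily:
    """The family of ``n`` thresholds used for the averaged reconstruction."""

    a_l: float                 # lower step limit = Min(A)
    a_u: float                 # upper step limit = Max(A)/3
    n: int
    delta_h: float             # step between consecutive step values
    steps: np.ndarray          # er_i, inclusive from a_l to a_u
    thresholds: np.ndarray     # T_wbc_i, strictly increasing (after clipping
                               # they may saturate at Max(A))


def generate_wbc_thresholds(
    image: np.ndarray, T_nc0: float, n: int = 10
) -> WBCThresholdFamily:
    """Build the WBC threshold family from the image extremes and the
    nucleus initial value (see module docstring).

    Raises
    ------
    DegenerateInputError
        For a constant image (no intensity range to step over).
    """
    if n < 2:
        raise ParameterError(f"n must be >= 2, got {n}")
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        raise DegenerateInputError("constant image: no threshold interval")
    a_l, a_u = lo, hi / 3.0
    delta_h = (a_u - a_l) / (n - 1)
    steps = a_l + delta_h * np.arange(n)
    base = (hi + T_nc0) / 2.0
    thresholds = base + steps
    if (thresholds > hi).any():
        warnings.warn(
            f"{int((thresholds > hi).sum())} of {n} thresholds exceed Max(A)="
            f"{hi:.4f}; clipping",
            stacklevel=2,
        )
        thresholds = np.minimum(thresholds, hi)
    return WBCThresholdFamily(
        a_l=a_l, a_u=a_u, n=n, delta_h=delta_h, steps=steps,
        thresholds=thresholds,
    )


def threshold_image(image: np.ndarray, T: float) -> np.ndarray:
    """Floor-threshold: pixels at or below ``T`` are raised to ``T``;
    brighter pixels are unchanged.  The output dominates the input
    pointwise."""
    if not 0.0 <= T <= 1.0:
        raise ParameterError(f"T must be in [0, 1], got {T}")
    image = np.asarray(image, dtype=np.float64)
    return np.where(image <= T, T, image)


def average_reconstruction(
    image: np.ndarray, family: WBCThresholdFamily
) -> np.ndarray:
    """Pixel-wise mean of the ``n`` floor-thresholded copies of the image.

    Equivalent to ``mean_i max(f, T_i)`` per pixel; the output dominates
    the input pointwise.
    """
    if family.n < 1:
        raise ParameterError("empty threshold family")
    image = np.asarray(image, dtype=np.float64)
    acc = np.zeros_like(image)
    for t in family.thresholds:
        acc += np.maximum(image, t)
    return acc / family.n


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: the histogram bin maximizing the between-class
    variance over ``nbins`` equal-width bins spanning [0, 1].

    Returns the center of the last bin of the dark class; pixels with
    ``f <= t`` belong to the dark class.  Ties resolve to the smallest
    bin index.

    Raises
    ------
    DegenerateInputError
        For a constant image (a single occupied bin has no split).
    """
    image = np.asarray(image, dtype=np.float64)
    counts, edges = np.histogram(image, bins=nbins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 2:
        raise DegenerateInputError("constant image: Otsu threshold undefined")
    total = counts.sum()
    w0 = np.cumsum(counts)
    w1 = total - w0
    mass = np.cumsum(counts * centers)
    mu0 = np.divide(mass, w0, out=np.zeros_like(mass), where=w0 > 0)
    mu1 = np.divide(mass[-1] - mass, w1, out=np.zeros_like(mass), where=w1 > 0)
    # between-class variance for a split after each bin; the last split is
    # degenerate (empty upper class)
    bcv = w0[:-1] * w1[:-1] * (mu0[:-1] - mu1[:-1]) ** 2
    idx = int(np.argmax(bcv))
    return float(centers[idx])


def select_seed_from_nucleus(nucleus: np.ndarray) -> tuple[int, int]:
    """A single (row, col) seed pixel inside the largest nucleus component.

    The seed is the floored centroid of the largest 8-connected component;
    for concave (e.g. multi-lobed) components whose centroid falls outside
    the mask, the nearest mask pixel to the centroid is used instead.
    """
    nucleus = np.asarray(nucleus, dtype=bool)
    if not nucleus.any():
        raise EmptyMaskError(
            "empty nucleus mask: run nucleus segmentation first"
        )
    labels = measure.label(nucleus, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    comp = labels == largest
    rows, cols = np.nonzero(comp)
    r, c = int(np.floor(rows.mean())), int(np.floor(cols.mean()))
    if comp[r, c]:
        return (r, c)
    d2 = (rows - r) ** 2 + (cols - c) ** 2
    k = int(np.argmin(d2))
    return (int(rows[k]), int(cols[k]))


def extract_wbc_by_seed(
    binary: np.ndarray, seed: tuple[int, int]
) -> np.ndarray:
    """Keep only the 8-connected foreground component containing ``seed``.

    Raises
    ------
    SeedNotOnForegroundError
        If the seed pixel is background; the exception carries the nearest
        foreground pixel as a suggestion.
    """
    binary = np.asarray(binary, dtype=bool)
    r, c = seed
    if not (0 <= r < binary.shape[0] and 0 <= c < binary.shape[1]):
        raise ParameterError(f"seed {seed} outside image bounds {binary.shape}")
    if not binary[r, c]:
        suggestion = None
        if binary.any():
            rows, cols = np.nonzero(binary)
            k = int(np.argmin((rows - r) ** 2 + (cols - c) ** 2))
            suggestion = (int(rows[k]), int(cols[k]))
        raise SeedNotOnForegroundError(seed, suggestion)
    labels = measure.label(binary, connectivity=2)
    return labels == labels[r, c]


def compute_cytoplasm(wbc: np.ndarray, nucleus: np.ndarray) -> np.ndarray:
    """Cytoplasm = WBC minus nucleus (set difference).

    Nucleus pixels outside the WBC are clipped from the subtraction with a
    warning — they indicate an inconsistent pair of masks.
    """
    wbc = np.asarray(wbc, dtype=bool)
    nucleus = np.asarray(nucleus, dtype=bool)
    if wbc.shape != nucleus.shape:
        raise ParameterError(
            f"shape mismatch: wbc {wbc.shape} vs nucleus {nucleus.shape}"
        )
    outside = nucleus & ~wbc
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} nucleus pixels lie outside the WBC mask; "
            "clipping them from the subtraction",
            stacklevel=2,
        )
    return wbc & ~nucleus


def segment_wbc(
    image: np.ndarray,
    nucleus: np.ndarray,
    n_thresholds: int = 10,
    params: NucleusParams | None = None,
    opening_radius: int = 2,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Full WBC pipeline for a cell well separated from red blood cells.

    Composes the averaged multi-threshold reconstruction, Otsu
    binarization (dark class = cell), morphological clean-up and
    nucleus-seeded extraction; the cytoplasm is derived by subtraction.
    The clean-up is a binary opening (disk of ``opening_radius`` pixels)
    followed by small-object removal and hole filling: the opening
    detaches thin noise bridges between the cell and dark background
    pixels, which would otherwise ride along with the seeded component.

    Returns ``(wbc_mask, cytoplasm_mask, otsu_t)`` where ``otsu_t`` is the
    Otsu threshold applied to the averaged reconstruction.
    """
    p = params or NucleusParams()
    image = np.asarray(image, dtype=np.float64)
    nucleus = np.asarray(nucleus, dtype=bool)
    if not nucleus.any():
        raise EmptyMaskError("empty nucleus mask: run nucleus segmentation first")
    t0 = compute_initial_value(image, p.n1, p.n2)
    family = generate_wbc_thresholds(image, t0, n_thresholds)
    averaged = average_reconstruction(image, family)
    t_otsu = otsu_threshold(averaged, p.nbins)
    binary = averaged <= t_otsu
    if opening_radius > 0:
        from skimage.morphology import disk

        binary = ndimage.binary_opening(binary, disk(opening_radius))
    binary = postprocess_mask(binary, int(round(p.min_area_frac * image.size)))
    seed = select_seed_from_nucleus(nucleus)
    wbc = extract_wbc_by_seed(binary, seed)
    cyto = compute_cytoplasm(wbc, nucleus)
    return wbc, cyto, t_otsu
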