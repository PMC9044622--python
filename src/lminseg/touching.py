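"""Fallback WBC segmentation when red blood cells touch the white cell.

The averaged-threshold strategy assumes the WBC is well separated from
the surrounding red blood cells; when they touch, the Otsu dark class
merges the cell with its neighbours.  Two classical fallbacks are
provided, each followed by nucleus-seeded retention so only the white
cell survives:

* **Marker-controlled watershed** — Otsu-binarize the grayscale (dark
  class = cells), take the Euclidean distance transform of the
  foreground, place markers at the local maxima of the distance map (the
  minimum marker separation is chosen automatically as half the distance
  map's maximum), run the watershed, and keep the union of the basins
  that overlap the nucleus.  Over-segmentation of the cell itself is
  harmless because the nucleus-overlap union re-merges its pieces.

* **SLIC superpixels** — cluster the image into boundary-adherent
  superpixels and retain those that either lie mostly inside the
  (dilated) nucleus or are at least as dark as the cytoplasm estimate
  sampled from a ring around the nucleus; the nucleus-seeded connected
  component of the union is the cell.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation
from skimage.feature import peak_local_max

from .errors import EmptyMaskError, ParameterError
from .nucleus import postprocess_mask
from .wbc import extract_wbc_by_seed, otsu_threshold, select_seed_from_nucleus

__all__ = ["segment_wbc_watershed", "segment_wbc_slic"]

#: radius (px) of the disk used to dilate the nucleus before retention tests
_NUCLEUS_DILATION = 3
#: intensity slack above the cytoplasm estimate for dark-superpixel retention
_CYTO_TOLERANCE = 0.08
#: width (px) of the ring around the nucleus used to estimate the
#: cytoplasm intensity
_CYTO_RING = 10


def segment_wbc_watershed(
    image: np.ndarray,
    nucleus: np.ndarray,
    min_area_frac: float = 0.005,
    min_distance: int | None = None,
) -> np.ndarray:
    """Separate a WBC from touching cells with a marker-controlled
    watershed on the distance transform (see module docstring).

    ``min_distance`` is the minimum separation between distance-map peaks
    used as markers; by default it is chosen automatically as half the
    maximum of the distance map.
    """
    image = np.asarray(image, dtype=np.float64)
    nucleus = np.asarray(nucleus, dtype=bool)
    if not nucleus.any():
        raise EmptyMaskError("empty nucleus mask: run nucleus segmentation first")
    t = otsu_threshold(image)
    foreground = image <= t
    if not foreground.any():
        raise EmptyMaskError("empty foreground after Otsu binarization")
    foreground = ndimage.binary_fill_holes(foreground)
    dist = ndimage.distance_transform_edt(foreground)
    if min_distance is None:
        min_distance = max(int(dist.max() / 2), 1)
    peaks = peak_local_max(
        dist, min_distance=min_distance, labels=foreground, exclude_border=False
    )
    markers = np.zeros(image.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        markers[np.unravel_index(np.argmax(dist), dist.shape)] = 1
    labels = segmentation.watershed(-dist, markers=markers, mask=foreground)
    keep = np.unique(labels[nucleus & (labels > 0)])
    mask = np.isin(labels, keep[keep > 0])
    mask = postprocess_mask(mask, int(round(min_area_frac * image.size)))
    seed = select_seed_from_nucleus(nucleus)
    if not mask[seed]:
        mask = mask | nucleus
    return extract_wbc_by_seed(mask, seed)


def segment_wbc_slic(
    image: np.ndarray,
    nucleus: np.ndarray,
    n_segments: int = 100,
    compactness: float | None = None,
    min_area_frac: float = 0.005,
) -> np.ndarray:
    """Segment a WBC with SLIC superpixels and nucleus-informed retention
    (see module docstring).

    ``image`` may be a gray image or an RGB image scaled to [0, 1]; SLIC
    runs on whatever is supplied, retention intensities use its gray form.
    ``compactness`` defaults to 10 for color input (SLIC works on the Lab
    scale, lightness 0-100) and 1 for [0, 1] gray input, which keep the
    color/spatial balance — and hence the boundary adherence — comparable
    across the two paths.
    """
    if n_segments < 4:
        raise ParameterError(f"n_segments must be >= 4, got {n_segments}")
    image = np.asarray(image, dtype=np.float64)
    nucleus = np.asarray(nucleus, dtype=bool)
    if not nucleus.any():
        raise EmptyMaskError("empty nucleus mask: run nucleus segmentation first")
    if image.ndim == 3:
        from .imgio import as_gray

        gray = as_gray(image if image.max() <= 1.0 else image / image.max())
        labels = segmentation.slic(
            image, n_segments=n_segments,
            compactness=10.0 if compactness is None else compactness,
            start_label=1, channel_axis=-1,
        )
    else:
        gray = image
        labels = segmentation.slic(
            image, n_segments=n_segments,
            compactness=1.0 if compactness is None else compactness,
            start_label=1, channel_axis=None,
        )

    dilated = morphology.dilation(nucleus, morphology.disk(_NUCLEUS_DILATION))
    ring = morphology.dilation(nucleus, morphology.disk(_CYTO_RING)) & ~nucleus
    cyto_cut = float(gray[ring].mean()) + _CYTO_TOLERANCE if ring.any() else 1.0

    keep = np.zeros(image.shape[:2], dtype=bool)
    for lab in np.unique(labels):
        region = labels == lab
        in_nucleus = (region & dilated).sum() > region.sum() / 2
        dark = gray[region].mean() <= cyto_cut
        if in_nucleus or dark:
            keep |= region
    keep = ndimage.binary_fill_holes(keep)
    seed = select_seed_from_nucleus(nucleus)
    if not keep[seed]:
        keep = keep | nucleus
    mask = extract_wbc_by_seed(keep, seed)
    return postprocess_mask(mask, int(round(min_area_frac * keep.size)))
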