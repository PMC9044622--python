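"""Histogram construction, smoothing and first peak/valley localization.

The nucleus threshold is estimated from the first local maximum and the
first local minimum of a smoothed, spline-interpolated image histogram.
The search works on the leading part of the histogram (by default its
first half), after removing the long flat tail of empty bins that dark
stains typically leave at intensity zero.  When no peak/valley pair exists
in the current segment, the segment end is extended by a fixed increment
and the search restarts, until the full histogram is exhausted.

The smoothing is a Savitzky–Golay filter.  Turning points are detected by
neighbor comparison on the smoothed bin values — the resolution at which
thresholds are reported — which equals sampling the cubic interpolating
spline at its knots while staying immune to spline ringing at sharp count
jumps; :func:`interpolate_segment` exposes the dense spline for plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.interpolate import make_interp_spline
from scipy.signal import savgol_filter

from .errors import (
    ExtremaNotFoundError,
    NoBimodalStructureError,
    NoMassError,
    ParameterError,
)

__all__ = [
    "Histogram",
    "TrimmedSegment",
    "SmoothedSegment",
    "ExtremaPair",
    "compute_histogram",
    "trim_flat_tail",
    "smooth_counts",
    "find_first_extrema",
    "iter_extrema_pairs",
    "search_extrema_with_extension",
    "interpolate_segment",
    "dump_debug_csv",
]

#: dense-sampling factor for extrema localization on the spline
_DENSITY = 10
#: segment-end growth per retry, as a fraction of the bin count
_EXTENSION_FRACTION = 0.1


@dataclass(frozen=True)
class Histogram:
    """Intensity histogram over equal-width bins spanning [0, 1]."""

    bin_centers: np.ndarray
    counts: np.ndarray

    @property
    def nbins(self) -> int:
        return len(self.counts)

    def __post_init__(self):
        if len(self.bin_centers) != len(self.counts):
            raise ParameterError("bin_centers and counts must have equal length")


@dataclass(frozen=True)
class TrimmedSegment:
    """A contiguous run of histogram bins with the leading flat tail removed."""

    knots: np.ndarray       # bin centers, strictly increasing
    counts: np.ndarray      # raw counts at those knots
    start: int              # index of the first knot in the parent histogram
    end: int                # exclusive end index in the parent histogram


@dataclass(frozen=True)
class SmoothedSegment:
    """Savitzky–Golay-smoothed frequencies on a contiguous knot run."""

    knots: np.ndarray
    values: np.ndarray
    spline_degree: int = 3
    segment_end: int = -1   # exclusive end index in the parent histogram


@dataclass(frozen=True)
class ExtremaPair:
    """The first local maximum and the following first local minimum of the
    spline through a smoothed histogram segment, snapped to knots."""

    x_c: float          # intensity of the first local maximum
    x_c1: float         # intensity of the first local minimum after it
    index_max: int      # knot index of x_c
    index_min: int      # knot index of x_c1

    def __post_init__(self):
        if not self.index_max < self.index_min:
            raise ParameterError("local maximum must precede local minimum")


def compute_histogram(image: np.ndarray, nbins: int = 256) -> Histogram:
    """Histogram of a [0, 1] gray image over ``nbins`` equal-width bins.

    The counts always sum to the pixel total.
    """
    if nbins < 8:
        raise ParameterError(f"nbins must be >= 8, got {nbins}")
    image = np.asarray(image, dtype=np.float64)
    counts, edges = np.histogram(image, bins=nbins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Histogram(bin_centers=centers, counts=counts)


def trim_flat_tail(
    hist: Histogram,
    segment_fraction: float = 0.5,
    flat_threshold: int = 0,
    segment_end: int | None = None,
) -> TrimmedSegment:
    """Select the leading ``segment_fraction`` of the histogram (or the bins
    up to ``segment_end`` if given) and drop the maximal leading run of flat
    bins (counts <= ``flat_threshold``).

    Raises
    ------
    NoMassError
        If every bin in the segment is flat; the caller should extend the
        segment.
    """
    if hist.nbins == 0:
        raise ParameterError("empty histogram")
    if segment_end is None:
        segment_end = int(np.ceil(segment_fraction * hist.nbins))
    segment_end = min(max(segment_end, 1), hist.nbins)
    counts = hist.counts[:segment_end]
    above = np.flatnonzero(counts > flat_threshold)
    if above.size == 0:
        raise NoMassError(
            f"no counts above {flat_threshold} in the first {segment_end} bins"
        )
    start = int(above[0])
    return TrimmedSegment(
        knots=hist.bin_centers[start:segment_end],
        counts=counts[start:],
        start=start,
        end=segment_end,
    )


def smooth_counts(
    raw, window: int = 11, polyorder: int = 3
) -> np.ndarray:
    """Savitzky–Golay smoothing of a count sequence.

    The filter preserves the general tendency of the histogram while
    removing high-frequency count noise.  If the sequence is shorter than
    ``window``, the window is reduced to the largest valid odd value (with
    ``polyorder`` lowered if necessary) and a warning is issued.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if window % 2 == 0:
        raise ParameterError(f"window must be odd, got {window}")
    if len(raw) < window:
        window = len(raw) if len(raw) % 2 == 1 else len(raw) - 1
        if window < 1:
            raise ParameterError("sequence too short to smooth")
        warnings.warn(
            f"sequence shorter than smoothing window; reduced window to {window}",
            stacklevel=2,
        )
    if polyorder >= window:
        polyorder = window - 1
    return savgol_filter(raw, window_length=window, polyorder=polyorder)


def interpolate_segment(segment: SmoothedSegment, density: int = _DENSITY):
    """Cubic-spline resampling of a smoothed segment at ``density`` times
    the knot spacing, for plotting/debug dumps of the fitted curve."""
    knots, values = segment.knots, segment.values
    k = min(segment.spline_degree, len(knots) - 1)
    spline = make_interp_spline(knots, values, k=k)
    xs = np.linspace(knots[0], knots[-1], max(len(knots) * density, 20))
    return xs, spline(xs)


def _extrema_pairs_of(segment: SmoothedSegment) -> list[ExtremaPair]:
    """All (max, min) turning-point pairs of a segment, in knot order.

    Turning points are found by neighbor comparison on the smoothed knot
    values — equivalent to sampling the interpolating spline at its knots,
    which is the resolution thresholds are reported at, while avoiding the
    spline's ringing at sharp count jumps.  Each local maximum is paired
    with the first local minimum following it; plateaus resolve to their
    smallest index.
    """
    values = np.asarray(segment.values, dtype=np.float64)
    knots = segment.knots
    n = len(values)
    if n < 3:
        return []

    d = np.diff(values)
    sign = np.sign(d)
    # propagate over exact plateaus so a flat top still turns exactly once
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]

    def plateau_start(idx: int) -> int:
        while idx > 0 and values[idx - 1] == values[idx]:
            idx -= 1
        return idx

    maxima, minima = [], []
    for i in range(len(sign) - 1):
        if sign[i] > 0 and sign[i + 1] < 0:
            maxima.append(plateau_start(i + 1))
        elif sign[i] < 0 and sign[i + 1] > 0:
            minima.append(plateau_start(i + 1))
    minima = np.asarray(minima)

    pairs: list[ExtremaPair] = []
    for i_max in maxima:
        later = minima[minima > i_max] if minima.size else minima
        if len(later) == 0:
            continue
        i_min = int(later[0])
        pairs.append(
            ExtremaPair(
                x_c=float(knots[i_max]),
                x_c1=float(knots[i_min]),
                index_max=int(i_max),
                index_min=i_min,
            )
        )
    return pairs


def find_first_extrema(segment: SmoothedSegment) -> ExtremaPair:
    """First strict local maximum followed by the first strict local
    minimum of the spline through ``segment``, in increasing knot order.

    Raises
    ------
    ExtremaNotFoundError
        If no such pair exists (monotone or degenerate segment); the caller
        should extend the segment and retry.
    """
    pairs = _extrema_pairs_of(segment)
    if not pairs:
        raise ExtremaNotFoundError("no local maximum/minimum pair in segment")
    return pairs[0]


def iter_extrema_pairs(
    hist: Histogram,
    segment_fraction: float = 0.5,
    flat_threshold: int = 0,
    window: int = 11,
    polyorder: int = 3,
    spline_degree: int = 3,
) -> Iterator[ExtremaPair]:
    """Yield peak/valley pairs in knot order, extending the search segment
    as needed.

    Starts from the trimmed leading ``segment_fraction`` of the histogram;
    whenever the current segment yields no new pair the segment end grows
    by ``ceil(0.1 * nbins)`` bins, until the full histogram is covered.
    Pairs already yielded for a shorter segment are not repeated (knot
    indices are global to the histogram).
    """
    nbins = hist.nbins
    increment = int(np.ceil(_EXTENSION_FRACTION * nbins))
    segment_end = int(np.ceil(segment_fraction * nbins))
    seen: set[tuple[int, int]] = set()
    while True:
        try:
            trimmed = trim_flat_tail(
                hist, flat_threshold=flat_threshold, segment_end=segment_end
            )
        except NoMassError:
            trimmed = None
        if trimmed is not None and len(trimmed.knots) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                values = smooth_counts(trimmed.counts, window, polyorder)
            segment = SmoothedSegment(
                knots=trimmed.knots,
                values=values,
                spline_degree=spline_degree,
                segment_end=trimmed.end,
            )
            for pair in _extrema_pairs_of(segment):
                key = (pair.index_max + trimmed.start, pair.index_min + trimmed.start)
                if key in seen:
                    continue
                seen.add(key)
                yield ExtremaPair(
                    x_c=pair.x_c,
                    x_c1=pair.x_c1,
                    index_max=key[0],
                    index_min=key[1],
                )
        if segment_end >= nbins:
            return
        segment_end = min(segment_end + increment, nbins)


def dump_debug_csv(image: np.ndarray, path_prefix, nbins: int = 256,
                   segment_fraction: float = 0.5, flat_threshold: int = 0,
                   window: int = 11, polyorder: int = 3) -> None:
    """Write the raw histogram, the trimmed/smoothed segment and the dense
    spline resampling as CSV files (``<prefix>_histogram.csv`` etc.) so
    the threshold-estimation curves can be plotted with any tool."""
    import csv

    hist = compute_histogram(image, nbins)
    with open(f"{path_prefix}_histogram.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["intensity", "count"])
        w.writerows(zip(hist.bin_centers, hist.counts))
    trimmed = trim_flat_tail(hist, segment_fraction, flat_threshold)
    values = smooth_counts(trimmed.counts, window, polyorder)
    with open(f"{path_prefix}_smoothed.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["intensity", "raw_count", "smoothed"])
        w.writerows(zip(trimmed.knots, trimmed.counts, values))
    segment = SmoothedSegment(knots=trimmed.knots, values=values,
                              segment_end=trimmed.end)
    xs, ys = interpolate_segment(segment)
    with open(f"{path_prefix}_spline.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["intensity", "spline"])
        w.writerows(zip(xs, ys))


def search_extrema_with_extension(hist: Histogram, **kwargs) -> ExtremaPair:
    """First peak/valley pair of the histogram, extending the search
    segment until one is found.

    Raises
    ------
    NoBimodalStructureError
        If the full histogram holds no such pair (e.g. a constant image).
    """
    for pair in iter_extrema_pairs(hist, **kwargs):
        return pair
    raise NoBimodalStructureError(
        "no local maximum/minimum pair in the full histogram"
    )
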