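"""Nucleus threshold estimation and segmentation.

The nucleus of a stained white blood cell is the darkest structure in a
single-cell blood-smear image, so it can be separated by a single
intensity threshold.  The threshold ``epsilon_t`` is estimated in two
steps:

1. An initial value ``T_nc0 = Max(A)/n1 + Min(A)/n2`` is computed from the
   image extremes (defaults ``n1 = n2 = 3`` put it near 1/3 for images
   whose minimum is close to zero).
2. The first local maximum ``x_c`` and following first local minimum
   ``x_c1`` of the smoothed histogram are located, and ``epsilon_t`` is
   placed near the valley by a branch rule controlled by a small margin
   ``Er``:

   * (a) is the validity check ``x_c < T_nc0`` — the threshold must lie
     after the first peak;
   * (b) ``|T_nc0 - x_c1| <= Er``  → ``epsilon_t = (T_nc0 + x_c1) / 2``;
   * (c) ``|T_nc0 - x_c1| > Er`` and ``T_nc0 > x_c1``
     → ``epsilon_t = (T_nc0 + x_c1 + Er) / 2``;
   * (d) ``|T_nc0 - x_c1| > Er`` and ``T_nc0 < x_c1``
     → ``epsilon_t = (T_nc0 + x_c1 - Er) / 2``.

   Equality ``|T_nc0 - x_c1| = Er`` is folded into branch (b): the three
   formulas coincide there, so the choice is value-neutral.

When no valid peak/valley pair exists (constant or unimodal images, or
every pair failing check (a)), the method falls back to
``epsilon_t = T_nc0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import ConditionViolation, ParameterError
from .histmodel import ExtremaPair, compute_histogram, iter_extrema_pairs

__all__ = [
    "NucleusParams",
    "ThresholdEstimate",
    "compute_initial_value",
    "estimate_threshold",
    "reconstruct_nucleus_image",
    "binarize_nucleus",
    "postprocess_mask",
    "segment_nucleus",
]


@dataclass(frozen=True)
class NucleusParams:
    """Tunable parameters of the nucleus pipeline with their defaults."""

    er: float = 0.07            # branch-rule margin, intensity units
    n1: int = 3                 # divisor of Max(A) in the initial value
    n2: int = 3                 # divisor of Min(A) in the initial value
    nbins: int = 256            # histogram bins over [0, 1]
    segment_fraction: float = 0.5
    flat_threshold: int = 0     # counts at or below this are "flat tail"
    window: int = 11            # Savitzky–Golay window (odd)
    polyorder: int = 3          # Savitzky–Golay polynomial order
    min_area_frac: float = 0.005  # small-object cutoff, fraction of image area

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ParameterError("n1 and n2 must be >= 1")
        if self.er <= 0:
            raise ParameterError("er must be > 0")


@dataclass(frozen=True)
class ThresholdEstimate:
    """Audit record of one nucleus threshold estimation."""

    T_nc0: float
    n1: int
    n2: int
    x_c: float | None
    x_c1: float | None
    Er: float
    epsilon_t: float
    branch: str                      # one of {"b", "c", "d", "fallback"}

    def to_dict(self) -> dict:
        return {
            "T_nc0": self.T_nc0,
            "n1": self.n1,
            "n2": self.n2,
            "x_c": self.x_c,
            "x_c1": self.x_c1,
            "Er": self.Er,
            "epsilon_t": self.epsilon_t,
            "branch": self.branch,
        }


def compute_initial_value(image: np.ndarray, n1: int = 3, n2: int = 3) -> float:
    """Initial search value ``T_nc0 = Max(A)/n1 + Min(A)/n2``.

    Warns when the result falls outside the open interval
    ``(Min(A), Max(A))``, which can only happen for near-constant images
    or unusual ``n1, n2``.
    """
    if n1 < 1 or n2 < 1:
        raise ParameterError(f"n1 and n2 must be >= 1, got {n1}, {n2}")
    image = np.asarray(image, dtype=np.float64)
    lo, hi = float(image.min()), float(image.max())
    t = hi / n1 + lo / n2
    if not lo < t < hi:
        warnings.warn(
            f"initial value {t:.4f} lies outside the open intensity range "
            f"({lo:.4f}, {hi:.4f})",
            stacklevel=2,
        )
    return t


def estimate_threshold(
    T_nc0: float, extrema: ExtremaPair, Er: float = 0.07, n1: int = 3, n2: int = 3
) -> ThresholdEstimate:
    """Place the nucleus threshold near the histogram valley by the
    branch rule (see module docstring).

    Raises
    ------
    ConditionViolation
        If the validity check (a) ``x_c < T_nc0`` fails; the caller should
        try the next peak/valley pair, and fall back to
        ``epsilon_t = T_nc0`` if none remains.
    """
    if Er <= 0:
        raise ParameterError(f"Er must be > 0, got {Er}")
    x_c, x_c1 = extrema.x_c, extrema.x_c1
    if not x_c < T_nc0:
        raise ConditionViolation(
            f"first local maximum {x_c:.4f} does not precede T_nc0 {T_nc0:.4f}"
        )
    diff = T_nc0 - x_c1
    if abs(diff) <= Er:
        branch, eps = "b", (T_nc0 + x_c1) / 2.0
    elif diff > 0:
        branch, eps = "c", (T_nc0 + x_c1 + Er) / 2.0
    else:
        branch, eps = "d", (T_nc0 + x_c1 - Er) / 2.0
    return ThresholdEstimate(
        T_nc0=T_nc0, n1=n1, n2=n2, x_c=x_c, x_c1=x_c1, Er=Er,
        epsilon_t=eps, branch=branch,
    )


def reconstruct_nucleus_image(image: np.ndarray, epsilon_t: float) -> np.ndarray:
    """Flatten everything at or below the threshold to the image minimum;
    leave brighter pixels untouched.  Idempotent for a fixed threshold."""
    if not 0.0 <= epsilon_t <= 1.0:
        raise ParameterError(f"epsilon_t must be in [0, 1], got {epsilon_t}")
    image = np.asarray(image, dtype=np.float64)
    return np.where(image <= epsilon_t, image.min(), image)


def binarize_nucleus(image: np.ndarray, epsilon_t: float) -> np.ndarray:
    """Binary nucleus mask: foreground where intensity <= ``epsilon_t``
    (the nucleus is the dark class).  Warns on all-foreground or
    all-background results, which indicate a suspicious threshold."""
    image = np.asarray(image, dtype=np.float64)
    mask = image <= epsilon_t
    if mask.all() or not mask.any():
        state = "all-foreground" if mask.all() else "all-background"
        warnings.warn(f"{state} mask at threshold {epsilon_t:.4f}", stacklevel=2)
    return mask


def postprocess_mask(mask: np.ndarray, min_object_area: int = 0) -> np.ndarray:
    """Remove 8-connected components smaller than ``min_object_area``
    pixels and fill fully enclosed holes."""
    mask = np.asarray(mask, dtype=bool)
    if min_object_area > 1:
        mask = morphology.remove_small_objects(
            mask, max_size=min_object_area - 1, connectivity=2
        )
    return ndimage.binary_fill_holes(mask)


def segment_nucleus(
    image: np.ndarray, params: NucleusParams | None = None
) -> tuple[np.ndarray, ThresholdEstimate]:
    """Full nucleus pipeline: histogram → peak/valley search with segment
    extension → initial value → branch rule → binarize → post-process.

    Returns the binary nucleus mask and the full threshold-estimate record
    for audit.  Peak/valley pairs failing check (a) are skipped in knot
    order; if none is usable the estimate falls back to
    ``epsilon_t = T_nc0`` with branch ``"fallback"``.
    """
    p = params or NucleusParams()
    image = np.asarray(image, dtype=np.float64)
    t0 = compute_initial_value(image, p.n1, p.n2)
    hist = compute_histogram(image, p.nbins)

    estimate: ThresholdEstimate | None = None
    for pair in iter_extrema_pairs(
        hist,
        segment_fraction=p.segment_fraction,
        flat_threshold=p.flat_threshold,
        window=p.window,
        polyorder=p.polyorder,
    ):
        try:
            estimate = estimate_threshold(t0, pair, p.er, p.n1, p.n2)
            break
        except ConditionViolation:
            continue
    if estimate is None:
        estimate = ThresholdEstimate(
            T_nc0=t0, n1=p.n1, n2=p.n2, x_c=None, x_c1=None, Er=p.er,
            epsilon_t=t0, branch="fallback",
        )

    mask = binarize_nucleus(image, estimate.epsilon_t)
    min_area = int(round(p.min_area_frac * image.size))
    mask = postprocess_mask(mask, min_area)
    return mask, estimate
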