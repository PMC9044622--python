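"""Exception hierarchy for the segmentation pipeline.

All library-specific failures derive from :class:`LminsegError` so callers
can catch pipeline problems without masking programming errors.
"""

from __future__ import annotations


class LminsegError(Exception):
    """Base class for all lminseg failures."""


class DegenerateInputError(LminsegError, ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. a constant image, a zero-sized image)."""


class FormatError(LminsegError, ValueError):
    """A file does not follow the expected encoding convention
    (e.g. a ground-truth mask with more than three gray levels)."""


class ParameterError(LminsegError, ValueError):
    """A parameter violates its documented range."""


class NoMassError(LminsegError):
    """The selected histogram segment contains no counts above the
    flatness threshold; the caller should extend the segment."""


class ExtremaNotFoundError(LminsegError):
    """No (local maximum, local minimum) pair exists in the current
    histogram segment; the caller should extend the segment."""


class NoBimodalStructureError(LminsegError):
    """The full histogram was exhausted without finding a peak/valley
    pair; the image has no exploitable bimodal structure."""


class ConditionViolation(LminsegError):
    """The ordering precondition x_c < T_nc0 failed for the candidate
    extrema pair; the caller should try the next pair."""


class EmptyMaskError(LminsegError):
    """An operation that requires a non-empty mask received an empty one."""


class SeedNotOnForegroundError(LminsegError):
    """The seed pixel fell on background during seeded extraction.

    Attributes
    ----------
    suggestion : tuple[int, int] | None
        Nearest foreground pixel to the offending seed, if any exists.
    """

    def __init__(self, seed, suggestion=None):
        self.seed = tuple(seed)
        self.suggestion = None if suggestion is None else tuple(suggestion)
        msg = f"seed {self.seed} not on foreground"
        if self.suggestion is not None:
            msg += f"; nearest foreground pixel is {self.suggestion}"
        super().__init__(msg)
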