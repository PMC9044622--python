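"""Histogram building, flat-tail trimming, smoothing and extrema search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lminseg import histmodel
from lminseg.errors import (
    ExtremaNotFoundError,
    NoBimodalStructureError,
    NoMassError,
)
from lminseg.histmodel import (
    Histogram,
    SmoothedSegment,
    compute_histogram,
    find_first_extrema,
    search_extrema_with_extension,
    smooth_counts,
    trim_flat_tail,
)


def brute_force_first_pair(values):
    """Independent oracle: first interior neighbor-comparison maximum,
    then the first interior minimum after it.  Returns (i_max, i_min) or
    None."""
    v = np.asarray(values, float)
    i_max = None
    for i in range(1, len(v) - 1):
        if v[i - 1] < v[i] > v[i + 1]:
            i_max = i
            break
    if i_max is None:
        return None
    for j in range(i_max + 1, len(v) - 1):
        if v[j - 1] > v[j] < v[j + 1]:
            return (i_max, j)
    return None


class TestComputeHistogram:
    def test_constant_image_single_bin(self):
        img = np.full((10, 10), 0.5)
        h = compute_histogram(img, nbins=256)
        assert np.count_nonzero(h.counts) == 1
        assert h.counts.sum() == 100

    def test_uniform_ramp_all_ones(self):
        img = (np.arange(256) / 255.0).reshape(16, 16)
        h = compute_histogram(img, nbins=256)
        # each 8-bit level occupies its own bin exactly once
        assert h.counts.max() <= 2 and h.counts.sum() == 256
        assert np.count_nonzero(h.counts) >= 255

    def test_conservation(self, rng):
        img = rng.random((37, 23))
        h = compute_histogram(img)
        assert h.counts.sum() == img.size

    def test_nbins_floor(self):
        with pytest.raises(Exception):
            compute_histogram(np.zeros((4, 4)), nbins=4)


class TestTrimFlatTail:
    def _hist(self, counts):
        counts = np.asarray(counts)
        centers = (np.arange(len(counts)) + 0.5) / len(counts)
        return Histogram(bin_centers=centers, counts=counts)

    def test_leading_zeros_removed(self):
        h = self._hist([0, 0, 0, 5, 9, 4, 1, 0, 0, 0, 0, 0])
        seg = trim_flat_tail(h)  # first half = 6 bins
        assert seg.start == 3
        np.testing.assert_array_equal(seg.counts, [5, 9, 4])

    def test_no_leading_zeros_identity(self):
        h = self._hist([3, 5, 9, 4, 1, 1, 0, 0])
        seg = trim_flat_tail(h)
        assert seg.start == 0
        np.testing.assert_array_equal(seg.counts, [3, 5, 9, 4])

    def test_flat_first_half_signals_no_mass(self):
        h = self._hist([0, 0, 0, 0, 1, 2, 3, 4])
        with pytest.raises(NoMassError):
            trim_flat_tail(h)

    def test_never_removes_counted_bin(self, rng):
        counts = rng.integers(0, 20, 64)
        h = self._hist(counts)
        try:
            seg = trim_flat_tail(h)
        except NoMassError:
            return
        dropped = counts[: seg.start]
        assert (dropped <= 0).all()


class TestSmoothCounts:
    def test_constant_preserved(self):
        out = smooth_counts(np.full(20, 7.0))
        np.testing.assert_allclose(out, 7.0)

    def test_linear_ramp_preserved(self):
        ramp = np.arange(30, dtype=float)
        np.testing.assert_allclose(smooth_counts(ramp, polyorder=1), ramp, atol=1e-9)

    def test_noise_variance_reduced_trend_kept(self, rng):
        x = np.linspace(0, 1, 200)
        clean = np.exp(-((x - 0.3) ** 2) / 0.01) + 0.7 * np.exp(-((x - 0.7) ** 2) / 0.01)
        noisy = clean + rng.normal(0, 0.05, x.size)
        smoothed = smooth_counts(noisy)
        assert np.var(np.diff(smoothed)) < np.var(np.diff(noisy))
        assert np.corrcoef(noisy, smoothed)[0, 1] >= 0.8

    def test_short_sequence_window_reduced_with_warning(self):
        with pytest.warns(UserWarning, match="reduced window"):
            out = smooth_counts(np.array([1.0, 2.0, 3.0, 2.0, 1.0]), window=11)
        assert len(out) == 5


class TestFindFirstExtrema:
    def _segment(self, knots, values):
        return SmoothedSegment(knots=np.asarray(knots, float),
                               values=np.asarray(values, float))

    def test_simple_bimodal_sequence(self):
        pair = find_first_extrema(
            self._segment([0.1, 0.2, 0.3, 0.4, 0.5], [1, 3, 2, 4, 1])
        )
        assert pair.x_c == pytest.approx(0.2)
        assert pair.x_c1 == pytest.approx(0.3)

    def test_monotone_has_no_extrema(self):
        with pytest.raises(ExtremaNotFoundError):
            find_first_extrema(self._segment([0.1, 0.2, 0.3, 0.4], [1, 2, 3, 4]))

    def test_max_without_following_min_not_found(self):
        with pytest.raises(ExtremaNotFoundError):
            find_first_extrema(self._segment([0.1, 0.2, 0.3, 0.4], [5, 2, 7, 1]))

    def test_ordering_invariant(self, rng):
        for _ in range(50):
            values = rng.random(12)
            seg = self._segment(np.linspace(0.1, 0.9, 12), values)
            try:
                pair = find_first_extrema(seg)
            except ExtremaNotFoundError:
                continue
            assert pair.index_max < pair.index_min
            assert pair.x_c < pair.x_c1

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(
            st.integers(min_value=0, max_value=50), min_size=6, max_size=25
        ).filter(lambda v: all(a != b for a, b in zip(v, v[1:])))
    )
    def test_matches_brute_force_on_plateau_free_sequences(self, values):
        """Spline extrema agree with the neighbor-comparison oracle to
        within one knot spacing on plateau-free sequences."""
        knots = np.linspace(0.0, 1.0, len(values))
        spacing = knots[1] - knots[0]
        expected = brute_force_first_pair(values)
        seg = SmoothedSegment(knots=knots, values=np.asarray(values, float))
        try:
            pair = find_first_extrema(seg)
        except ExtremaNotFoundError:
            pair = None
        if expected is not None and pair is not None:
            i_max, i_min = expected
            assert abs(pair.x_c - knots[i_max]) <= spacing + 1e-12
            assert abs(pair.x_c1 - knots[i_min]) <= spacing + 1e-12


class TestSearchWithExtension:
    def _image_from_values(self, values, counts):
        return np.repeat(values, counts).reshape(1, -1)

    def test_bimodal_found_first_pass(self, rng):
        img = np.clip(
            np.concatenate(
                [rng.normal(0.15, 0.03, 2000), rng.normal(0.4, 0.03, 3000)]
            ),
            0,
            1,
        ).reshape(50, 100)
        pair = search_extrema_with_extension(compute_histogram(img))
        assert 0.1 < pair.x_c < 0.25
        assert 0.2 < pair.x_c1 < 0.4

    def test_valley_past_midpoint_found_after_extension(self, rng):
        # modes at 0.45 and 0.75: the valley lies beyond the first half
        img = np.clip(
            np.concatenate(
                [rng.normal(0.45, 0.02, 3000), rng.normal(0.75, 0.02, 3000)]
            ),
            0,
            1,
        ).reshape(60, 100)
        pair = search_extrema_with_extension(compute_histogram(img))
        assert pair.x_c1 > 0.5

    def test_constant_image_no_bimodal_structure(self):
        img = np.full((20, 20), 0.5)
        with pytest.raises(NoBimodalStructureError):
            search_extrema_with_extension(compute_histogram(img))
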