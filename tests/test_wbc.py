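"""Threshold family, averaged reconstruction, Otsu, seeded extraction."""

import numpy as np
import pytest

from lminseg.errors import (
    DegenerateInputError,
    EmptyMaskError,
    ParameterError,
    SeedNotOnForegroundError,
)
from lminseg.imgio import trilevel_to_binary
from lminseg.metrics import evaluate_masks
from lminseg.nucleus import segment_nucleus
from lminseg.wbc import (
    average_reconstruction,
    compute_cytoplasm,
    extract_wbc_by_seed,
    generate_wbc_thresholds,
    otsu_threshold,
    segment_wbc,
    select_seed_from_nucleus,
    threshold_image,
)


def otsu_brute_force(image, nbins=256):
    """Independent oracle: naive loop maximizing between-class variance
    over every candidate split of a 256-bin histogram."""
    counts, edges = np.histogram(image, bins=nbins, range=(0.0, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best, best_t = -1.0, None
    total = counts.sum()
    for i in range(nbins - 1):
        w0 = counts[: i + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            bcv = 0.0
        else:
            mu0 = (counts[: i + 1] * centers[: i + 1]).sum() / w0
            mu1 = (counts[i + 1 :] * centers[i + 1 :]).sum() / w1
            bcv = w0 * w1 * (mu0 - mu1) ** 2
        if bcv > best:
            best, best_t = bcv, centers[i]
    return best_t


class TestThresholdFamily:
    def _full_range_image(self):
        return np.array([[0.0, 1.0], [0.5, 0.5]])

    def test_hand_evaluated_family_n5(self):
        fam = generate_wbc_thresholds(self._full_range_image(), T_nc0=1 / 3, n=5)
        assert fam.a_l == 0.0 and fam.a_u == pytest.approx(1 / 3)
        np.testing.assert_allclose(fam.steps, [0, 1 / 12, 1 / 6, 1 / 4, 1 / 3])
        np.testing.assert_allclose(
            fam.thresholds, [2 / 3, 0.75, 5 / 6, 11 / 12, 1.0]
        )

    def test_two_thresholds_are_endpoints(self):
        img = np.array([[0.0, 0.9]])
        fam = generate_wbc_thresholds(img, T_nc0=0.3, n=2)
        base = (0.9 + 0.3) / 2
        np.testing.assert_allclose(fam.thresholds, [base, base + 0.3])

    @pytest.mark.parametrize("n", [2, 5, 10, 50])
    def test_spacing_and_endpoint_invariants(self, n):
        img = np.array([[0.0, 0.9], [0.45, 0.2]])
        fam = generate_wbc_thresholds(img, T_nc0=0.3, n=n)
        assert fam.steps[0] == pytest.approx(fam.a_l)
        assert fam.steps[-1] == pytest.approx(fam.a_u)
        assert fam.delta_h * (n - 1) == pytest.approx(fam.a_u - fam.a_l)
        assert (np.diff(fam.thresholds) > 0).all()

    def test_clipping_warns(self):
        img = np.array([[0.0, 1.0]])
        with pytest.warns(UserWarning, match="clip"):
            fam = generate_wbc_thresholds(img, T_nc0=0.5, n=5)
        assert fam.thresholds.max() == 1.0

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            generate_wbc_thresholds(np.full((3, 3), 0.5), T_nc0=0.3, n=5)


class TestAveragedReconstruction:
    def test_floor_rule(self):
        img = np.array([[0.5, 0.9]])
        np.testing.assert_allclose(threshold_image(img, 0.7), [[0.7, 0.9]])

    def test_output_dominates_input(self, rng):
        img = rng.random((10, 10))
        for t in (0.0, 0.3, 0.99):
            assert (threshold_image(img, t) >= img).all()

    def test_mean_of_thresholds_for_dark_pixel(self):
        img = np.array([[0.0, 0.9], [0.05, 0.45]])
        fam = generate_wbc_thresholds(img, T_nc0=0.3, n=4)
        avg = average_reconstruction(img, fam)
        # the 0.05 pixel sits below every threshold
        assert avg[0, 0] == pytest.approx(fam.thresholds.mean())
        assert avg[1, 0] == pytest.approx(fam.thresholds.mean())
        assert (avg >= img).all()

    def test_pixel_above_all_thresholds_unchanged(self):
        img = np.array([[0.0, 0.9]])
        fam = generate_wbc_thresholds(img, T_nc0=0.1, n=3)
        avg = average_reconstruction(img, fam)
        assert avg[0, 1] == pytest.approx(0.9)


class TestOtsu:
    def test_two_valued_separation(self):
        img = np.concatenate([np.full(100, 0.2), np.full(100, 0.8)]).reshape(10, 20)
        t = otsu_threshold(img)
        assert 0.2 < t < 0.8

    def test_skewed_two_valued_separation(self):
        img = np.concatenate([np.full(190, 0.2), np.full(10, 0.8)]).reshape(10, 20)
        t = otsu_threshold(img)
        assert 0.2 < t < 0.8
        assert t == otsu_brute_force(img)

    def test_equals_brute_force_on_random_images(self, rng):
        for _ in range(20):
            img = np.clip(
                rng.normal(rng.uniform(0.3, 0.7), 0.15, (20, 20)), 0, 1
            )
            if np.unique(img).size < 2:
                continue
            assert otsu_threshold(img) == otsu_brute_force(img)

    def test_close_to_skimage(self, rng):
        from skimage.filters import threshold_otsu

        img = np.clip(
            np.concatenate(
                [rng.normal(0.3, 0.05, 300), rng.normal(0.7, 0.05, 300)]
            ),
            0,
            1,
        ).reshape(20, 30)
        assert otsu_threshold(img) == pytest.approx(
            threshold_otsu(img, nbins=256), abs=0.01
        )

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full((5, 5), 0.4))


class TestSeedSelection:
    def test_square_centroid(self):
        mask = np.zeros((20, 20), bool)
        mask[0:10, 0:10] = True
        assert select_seed_from_nucleus(mask) == (4, 4)

    def test_concave_component_seed_on_mask(self):
        mask = np.zeros((20, 20), bool)
        mask[2:18, 2:5] = True
        mask[2:5, 2:18] = True
        mask[15:18, 2:18] = True  # C shape; centroid falls in the gap
        seed = select_seed_from_nucleus(mask)
        assert mask[seed]

    def test_largest_component_wins(self):
        mask = np.zeros((30, 30), bool)
        mask[1:11, 1:11] = True     # 100 px
        mask[20:24, 20:25] = True   # 20 px
        seed = select_seed_from_nucleus(mask)
        assert seed[0] < 11 and seed[1] < 11

    def test_empty_mask_error(self):
        with pytest.raises(EmptyMaskError):
            select_seed_from_nucleus(np.zeros((5, 5), bool))


class TestSeededExtraction:
    def test_only_seed_component_kept(self):
        mask = np.zeros((20, 20), bool)
        mask[1:5, 1:5] = True
        mask[10:15, 10:15] = True
        out = extract_wbc_by_seed(mask, (2, 2))
        assert out[1:5, 1:5].all() and not out[10:15, 10:15].any()

    def test_seed_on_background_suggests_nearest(self):
        mask = np.zeros((10, 10), bool)
        mask[5:8, 5:8] = True
        with pytest.raises(SeedNotOnForegroundError) as exc:
            extract_wbc_by_seed(mask, (0, 0))
        assert exc.value.suggestion == (5, 5)

    def test_single_component_identity(self):
        mask = np.zeros((10, 10), bool)
        mask[2:6, 2:6] = True
        np.testing.assert_array_equal(extract_wbc_by_seed(mask, (3, 3)), mask)


class TestCytoplasm:
    def test_square_subtraction(self):
        wbc = np.zeros((20, 20), bool)
        wbc[4:16, 4:16] = True  # 144 px
        nuc = np.zeros((20, 20), bool)
        nuc[7:13, 7:13] = True  # 36 px
        cyto = compute_cytoplasm(wbc, nuc)
        assert cyto.sum() == 108

    def test_nucleus_equals_wbc_empty_cytoplasm(self):
        wbc = np.zeros((10, 10), bool)
        wbc[2:8, 2:8] = True
        assert not compute_cytoplasm(wbc, wbc).any()

    def test_nucleus_outside_wbc_clipped_with_warning(self):
        wbc = np.zeros((10, 10), bool)
        wbc[0:5, 0:5] = True
        nuc = np.zeros((10, 10), bool)
        nuc[3:8, 3:8] = True
        with pytest.warns(UserWarning, match="outside"):
            cyto = compute_cytoplasm(wbc, nuc)
        assert not (cyto & nuc).any()
        assert (cyto | (nuc & wbc)).sum() == wbc.sum()


class TestSegmentWBC:
    def test_recovers_synthetic_cell(self, separated_cell):
        _, gray, tri, _ = separated_cell
        nmask, _ = segment_nucleus(gray)
        with pytest.warns(UserWarning):  # top threshold clips at Max(A)
            wbc_mask, cyto, t = segment_wbc(gray, nmask)
        truth = trilevel_to_binary(tri, (255, 128))
        assert evaluate_masks(wbc_mask, truth).dsc >= 0.90
        assert 0.0 < t < 1.0

    def test_mask_algebra(self, separated_cell):
        _, gray, tri, _ = separated_cell
        nmask, _ = segment_nucleus(gray)
        with pytest.warns(UserWarning):
            wbc_mask, cyto, _ = segment_wbc(gray, nmask)
        assert not (cyto & nmask).any()
        assert (cyto <= wbc_mask).all()
        np.testing.assert_array_equal(cyto | (nmask & wbc_mask), wbc_mask)

    def test_empty_nucleus_rejected(self, separated_cell):
        _, gray, _, _ = separated_cell
        with pytest.raises(EmptyMaskError):
            segment_wbc(gray, np.zeros_like(gray, dtype=bool))
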