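"""Edge-driven segmentation: Sobel response, edge co-occurrence, LUT."""

import numpy as np
import pytest

from fibroquant.images import (
    GreyImage,
    LABEL_FIBROUS,
    LABEL_MUSCLE,
    TissueMask,
    quantize,
)
from fibroquant.phantom import PhantomSpec, generate_phantom
from fibroquant.segmentation import (
    SinglePeakFallbackWarning,
    bilateral_average,
    edge_cooccurrence_matrix,
    fibrous_muscle_ratio,
    label_leading_diagonal,
    lut_segment,
    segment_image,
    sobel_edge_strength,
)


class TestSobel:
    def test_constant_image_has_zero_response(self):
        img = np.full((16, 16), 7.0)
        assert sobel_edge_strength(img).magnitudes.max() == 0.0

    def test_step_edge_magnitude_matches_hand_convolution(self):
        # left half grey 0, right half grey 10; at an interior pixel whose
        # right neighbour column is the bright side, the horizontal kernel
        # sums to (1+2+1)*10 = 40 and the vertical response is zero.
        img = np.zeros((6, 6))
        img[:, 3:] = 10.0
        edges = sobel_edge_strength(img)
        assert edges.magnitudes[2, 2] == pytest.approx(40.0)
        assert edges.magnitudes[2, 0] == 0.0  # far from the step

    def test_rotating_the_image_rotates_the_magnitude(self, rng):
        img = rng.integers(0, 256, (20, 20)).astype(float)
        rotated = sobel_edge_strength(np.rot90(img)).magnitudes
        np.testing.assert_allclose(rotated, np.rot90(sobel_edge_strength(img).magnitudes))

    @pytest.mark.parametrize("c", [2.0, 0.5, 10.0])
    def test_response_is_linear_in_contrast(self, rng, c):
        img = rng.integers(0, 100, (12, 12)).astype(float)
        np.testing.assert_allclose(
            sobel_edge_strength(c * img).magnitudes,
            c * sobel_edge_strength(img).magnitudes,
        )

    def test_image_smaller_than_kernel_rejected(self):
        with pytest.raises(ValueError):
            sobel_edge_strength(np.zeros((2, 5)))


def _brute_force_ecm(q, norm, roi):
    """Independent pair enumeration with the same edge weighting rule."""
    G = int(q.max()) + 1
    counts = np.zeros((G, G))
    H, W = q.shape
    for r in range(H):
        for c in range(W):
            for dr, dc in ((0, 1), (1, 0)):
                r2, c2 = r + dr, c + dc
                if r2 >= H or c2 >= W:
                    continue
                if not (roi[r, c] and roi[r2, c2]):
                    continue
                w = 1.0 + 0.5 * (norm[r, c] + norm[r2, c2])
                counts[q[r, c], q[r2, c2]] += w
                counts[q[r2, c2], q[r, c]] += w
    return counts


class TestEdgeCooccurrence:
    def test_constant_image_concentrates_on_one_diagonal_cell(self):
        img = GreyImage(np.zeros((8, 8), dtype=int), levels=4)
        ecm = edge_cooccurrence_matrix(img, sobel_edge_strength(img))
        nz = np.argwhere(ecm.counts > 0)
        assert nz.tolist() == [[0, 0]]

    def test_matches_brute_force_enumeration(self):
        spec = PhantomSpec(
            target_ratio=0.25, image_height=32, image_width=32,
            grey_noise_sd=0.0, roi_margin=2, blob_scale=2.0,
        )
        out = generate_phantom(spec, seed=1)
        roi = out.roi
        q = quantize(out.image.pixels, 8, roi=roi)
        edges = sobel_edge_strength(out.image.pixels)
        peak = edges.magnitudes.max()
        norm = edges.magnitudes / peak
        expected = _brute_force_ecm(q.pixels, norm, roi)
        ecm = edge_cooccurrence_matrix(q, edges, roi=roi)
        np.testing.assert_allclose(ecm.counts, expected)

    def test_two_level_phantom_has_three_cell_classes(self):
        spec = PhantomSpec(
            target_ratio=0.25, image_height=64, image_width=64,
            grey_noise_sd=0.0, roi_margin=4,
        )
        out = generate_phantom(spec, seed=2)
        q = quantize(out.image.pixels, 8, roi=out.roi)
        ecm = edge_cooccurrence_matrix(q, sobel_edge_strength(out.image.pixels), roi=out.roi)
        a, b = 0, 7  # min-max quantization maps the two grey means to the ends
        nz = {tuple(ij) for ij in np.argwhere(ecm.counts > 0)}
        assert nz == {(a, a), (b, b), (a, b), (b, a)}

    def test_matrix_is_symmetric(self, rng):
        img = GreyImage(rng.integers(0, 16, (24, 24)), levels=16)
        ecm = edge_cooccurrence_matrix(img, sobel_edge_strength(img))
        np.testing.assert_allclose(ecm.counts, ecm.counts.T)

    def test_single_grey_level_image_rejected(self):
        img = GreyImage(np.zeros((8, 8), dtype=int), levels=2)
        with pytest.raises(ValueError):
            edge_cooccurrence_matrix(
                GreyImage(np.zeros((8, 8), dtype=int), levels=1),
                sobel_edge_strength(img),
            )


class TestLeadingDiagonalLabelling:
    @staticmethod
    def _two_level_image(lo, hi):
        px = np.full((32, 32), lo, dtype=int)
        px[:, 16:] = hi
        return GreyImage(px, levels=256)

    def test_peaks_sit_at_the_planted_grey_levels(self):
        img = self._two_level_image(40, 200)
        ecm = label_leading_diagonal(
            edge_cooccurrence_matrix(img, sobel_edge_strength(img))
        )
        assert ecm.diagonal_peaks == (40, 200)
        assert ecm.label_map[40] == LABEL_MUSCLE
        assert ecm.label_map[200] == LABEL_FIBROUS
        boundary = int(np.max(np.where(ecm.label_map == LABEL_MUSCLE)))
        assert 40 <= boundary < 200

    def test_brighter_peak_is_always_fibrous(self):
        # minority-bright and minority-dark images agree on the class of the
        # bright level: brightness, not area, decides the assignment
        for bright_cols in (8, 24):
            px = np.full((32, 32), 40, dtype=int)
            px[:, :bright_cols] = 200
            img = GreyImage(px, levels=256)
            ecm = label_leading_diagonal(
                edge_cooccurrence_matrix(img, sobel_edge_strength(img))
            )
            assert ecm.label_map[200] == LABEL_FIBROUS
            assert ecm.label_map[40] == LABEL_MUSCLE

    def test_single_tissue_image_falls_back_to_all_muscle(self):
        px = np.full((16, 16), 5, dtype=int)
        img = GreyImage(px, levels=16)
        ecm = edge_cooccurrence_matrix(img, sobel_edge_strength(img))
        with pytest.warns(SinglePeakFallbackWarning):
            labelled = label_leading_diagonal(ecm)
        mask = lut_segment(img, labelled)
        assert mask.fibrous_count == 0
        assert mask.muscle_count == 16 * 16

    def test_every_grey_level_receives_a_label(self):
        img = self._two_level_image(10, 100)
        ecm = label_leading_diagonal(
            edge_cooccurrence_matrix(img, sobel_edge_strength(img))
        )
        assert ecm.label_map.shape == (256,)
        assert set(np.unique(ecm.label_map)) <= {LABEL_MUSCLE, LABEL_FIBROUS}


class TestLutSegment:
    def test_noise_free_phantom_reproduces_truth_exactly(self):
        spec = PhantomSpec(target_ratio=0.25, grey_noise_sd=0.0)
        out = generate_phantom(spec, seed=4)
        mask, _ = segment_image(out.image, roi=out.roi, levels=64)
        np.testing.assert_array_equal(mask.labels, out.truth_mask.labels)

    def test_roi_excluding_fibrous_yields_zero_fibrous(self):
        spec = PhantomSpec(target_ratio=0.25, grey_noise_sd=0.0)
        out = generate_phantom(spec, seed=4)
        roi = out.roi & (out.truth_mask.labels == LABEL_MUSCLE)
        with pytest.warns(SinglePeakFallbackWarning):
            mask, _ = segment_image(out.image, roi=roi, levels=64)
        assert mask.fibrous_count == 0

    def test_noisy_phantom_agreement_at_least_98_percent(self):
        spec = PhantomSpec(target_ratio=0.23, grey_noise_sd=5.0)
        out = generate_phantom(spec, seed=6)
        mask, _ = segment_image(out.image, roi=out.roi, levels=64)
        roi = out.roi
        agree = np.mean(mask.labels[roi] == out.truth_mask.labels[roi])
        assert agree >= 0.98

    def test_lut_application_is_idempotent(self):
        spec = PhantomSpec(target_ratio=0.23)
        out = generate_phantom(spec, seed=8)
        roi = out.roi
        mask, ecm = segment_image(out.image, roi=roi, levels=64)
        # replace each pixel by its class-representative grey and re-apply
        lo, hi = ecm.diagonal_peaks
        relabelled = np.zeros(mask.shape, dtype=int)
        relabelled[mask.labels == LABEL_MUSCLE] = lo
        relabelled[mask.labels == LABEL_FIBROUS] = hi
        again = lut_segment(GreyImage(relabelled, levels=ecm.levels), ecm, roi=roi)
        np.testing.assert_array_equal(again.labels[roi], mask.labels[roi])

    def test_empty_roi_rejected(self):
        spec = PhantomSpec(target_ratio=0.2)
        out = generate_phantom(spec, seed=1)
        with pytest.raises(ValueError):
            segment_image(out.image, roi=np.zeros(out.image.shape, dtype=bool))

    def test_missing_label_map_rejected(self):
        img = GreyImage(np.zeros((8, 8), dtype=int), levels=4)
        ecm = edge_cooccurrence_matrix(
            GreyImage(np.arange(64).reshape(8, 8) % 4, levels=4),
            sobel_edge_strength(img),
        )
        with pytest.raises(ValueError):
            lut_segment(img, ecm)


class TestRatios:
    def test_ratio_is_direct_count_quotient(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[:10, :10] = LABEL_MUSCLE  # 100 muscle
        labels[:2, 10:20] = LABEL_FIBROUS  # 20 fibrous
        assert fibrous_muscle_ratio(TissueMask(labels)) == pytest.approx(0.2)

    def test_zero_fibrous_gives_zero(self):
        labels = np.full((5, 5), LABEL_MUSCLE, dtype=np.uint8)
        assert fibrous_muscle_ratio(TissueMask(labels)) == 0.0

    def test_no_muscle_is_an_error(self):
        labels = np.full((5, 5), LABEL_FIBROUS, dtype=np.uint8)
        with pytest.raises(ValueError):
            fibrous_muscle_ratio(TissueMask(labels))

    def test_truth_mask_round_trip_at_printed_target(self):
        spec = PhantomSpec(target_ratio=0.23, grey_noise_sd=0.0)
        out = generate_phantom(spec, seed=10)
        r = fibrous_muscle_ratio(out.truth_mask)
        assert r == pytest.approx(out.true_ratio)
        assert abs(r - 0.23) <= 2.0 / out.truth_mask.muscle_count

    def test_bilateral_average(self):
        assert bilateral_average(0.2, 0.3) == pytest.approx(0.25)
        assert bilateral_average(0.4, 0.4) == 0.4
        with pytest.raises(ValueError):
            bilateral_average(float("nan"), 0.1)
        with pytest.raises(ValueError):
            bilateral_average(-0.1, 0.1)


def test_full_pipeline_recovers_planted_ratio_over_seeds():
    """generate -> segment -> ratio: MAE < 0.02 over 20 seeded phantoms."""
    spec = PhantomSpec(target_ratio=0.23, grey_noise_sd=5.0)
    errors = []
    for seed in range(20):
        out = generate_phantom(spec, seed=seed)
        mask, _ = segment_image(out.image, roi=out.roi, levels=64)
        errors.append(abs(fibrous_muscle_ratio(mask) - out.true_ratio))
    assert np.mean(errors) < 0.02
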