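"""Segmentation chain vs analytic cases and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    flood_fill_label_oracle,
    opening_subtract_oracle,
    otsu_partition_oracle,
    partitions_equal,
    sliding_mean_oracle,
)
from spotscreen import (
    SceneSpec,
    SegmentationParams,
    binarize_and_clean,
    extract_features,
    label_components,
    render_field,
    segment_field,
    subtract_background,
    threshold_global_otsu,
    threshold_local_mean,
)
from spotscreen.metrics import detection_scores


class TestSubtractBackground:
    def test_constant_image_maps_to_zero(self):
        out = subtract_background(np.full((20, 20), 137.0), 5)
        assert np.all(out == 0)

    def test_single_impulse_preserved(self):
        img = np.full((15, 15), 50.0)
        img[7, 7] += 300.0
        out = subtract_background(img, 4)
        assert out[7, 7] == pytest.approx(300.0, abs=1.0)
        out[7, 7] = 0
        assert np.all(out <= 4.0)  # ball cannot leave more than ~h(1) residue

    def test_matches_brute_force_oracle_exactly(self, rng):
        for _ in range(5):
            img = rng.integers(0, 5000, size=(9, 9)).astype(np.float32)
            assert np.array_equal(subtract_background(img, 3), opening_subtract_oracle(img, 3))

    def test_output_never_exceeds_input(self, rng):
        img = rng.uniform(0, 65535, (40, 40))
        out = subtract_background(img, 10)
        assert np.all(out <= img + 1e-3)
        assert np.all(out >= 0)

    def test_second_pass_changes_little(self, default_field):
        """Opening idempotence makes background subtraction nearly
        idempotent: on a smooth noise-free image the second pass changes at
        most the ball-top discretization residue (~1 count); on a noisy
        rendered field the residue stays a negligible fraction of signal."""
        smooth = np.linspace(100, 160, 60)[None, :] * np.ones((60, 1))
        smooth[22:30, 22:30] += 2000.0
        once = subtract_background(smooth, 12)
        twice = subtract_background(once, 12)
        interior = np.abs(once - twice)[12:-12, 12:-12]
        assert np.max(interior) <= 1.0
        assert np.max(np.abs(once - twice)) <= 5.0  # border effects only

        img, _ = default_field
        once = subtract_background(img.channels["nuclei"].astype(float), 50)
        twice = subtract_background(once, 50)
        assert np.max(np.abs(once - twice)) <= 0.005 * once.max()

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((10, 10)), 0)
        with pytest.raises(ValueError):
            subtract_background(np.zeros((10, 10)), 20)


class TestOtsu:
    def test_bimodal_threshold_separates_modes(self):
        img = np.r_[np.full(100, 10.0), np.full(100, 200.0)].reshape(10, 20)
        t = threshold_global_otsu(img)
        assert 10.0 < t <= 200.0
        assert np.array_equal(img >= t, img == 200.0)

    def test_matches_exhaustive_search_oracle(self, rng):
        for _ in range(20):
            img = rng.integers(0, 65535, size=(64, 64)).astype(float)
            t = threshold_global_otsu(img)
            assert np.array_equal(img >= t, otsu_partition_oracle(img))

    def test_inversion_swaps_classes(self, rng):
        img = np.r_[rng.normal(300, 30, 500), rng.normal(3000, 200, 300)]
        img = img.reshape(40, 20)
        inv = img.max() + img.min() - img
        fg = img >= threshold_global_otsu(img)
        fg_inv = inv >= threshold_global_otsu(inv)
        assert np.array_equal(fg, ~fg_inv)

    def test_constant_image_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            threshold_global_otsu(np.full((8, 8), 5.0))


class TestLocalMean:
    def test_constant_image_all_false(self):
        assert not threshold_local_mean(np.full((30, 30), 42.0), 11).any()

    def test_bright_square_interior_detected(self):
        img = np.zeros((25, 25))
        img[10:15, 10:15] = 100.0
        mask = threshold_local_mean(img, 11, 0.0)
        assert mask[10:15, 10:15].all()

    def test_matches_sliding_window_oracle(self, rng):
        img = rng.uniform(0, 100, (17, 13))
        mask = threshold_local_mean(img, 5, 3.0)
        expect = img > sliding_mean_oracle(img, 5) + 3.0
        assert np.array_equal(mask, expect)

    def test_huge_offset_blanks_everything(self, rng):
        img = rng.uniform(0, 100, (20, 20))
        assert not threshold_local_mean(img, 7, 1e9).any()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            threshold_local_mean(np.zeros((10, 10)), 10)


class TestBinarizeAndClean:
    def test_background_only_field_is_empty(self):
        img, _ = render_field(SceneSpec(expected_cells=1e-9, seed=4))
        sub = subtract_background(img.channels["nuclei"].astype(float), 50)
        mask = binarize_and_clean(sub, SegmentationParams())
        assert not mask.any()

    def test_all_rendered_nuclei_survive(self):
        """A field of ~50 non-touching nuclei yields exactly one component
        per rendered cell."""
        img, truth = render_field(SceneSpec(seed=8, expected_cells=50))
        sub = subtract_background(img.channels["nuclei"].astype(float), 50)
        mask = binarize_and_clean(sub, SegmentationParams())
        labels = label_components(mask)
        assert truth.n_cells > 30
        assert labels.max() == truth.n_cells

    def test_small_speck_removed(self):
        img = np.zeros((64, 64))
        img[10:30, 10:30] = 4000.0  # real object
        img[50, 50] = 4000.0
        img[50, 51] = 4000.0  # 2-px speck
        mask = binarize_and_clean(img, SegmentationParams(min_area=40, opening_radius=0))
        labels = label_components(mask)
        assert labels.max() == 1
        assert not mask[50, 50]


class TestLabelComponents:
    def test_diagonal_connectivity_semantics(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        assert label_components(mask, 8).max() == 1
        assert label_components(mask, 4).max() == 2

    def test_empty_mask(self):
        assert label_components(np.zeros((5, 5), bool)).max() == 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_flood_fill_oracle(self, seed):
        r = np.random.default_rng(seed)
        mask = r.random((32, 32)) < 0.4
        for conn in (4, 8):
            got = label_components(mask, conn)
            ref = flood_fill_label_oracle(mask, conn)
            assert partitions_equal(got, ref)
            assert got.max() == ref.max()

    def test_labels_contiguous(self, rng):
        mask = rng.random((40, 40)) < 0.3
        labels = label_components(mask, 8)
        present = np.unique(labels[labels > 0])
        assert np.array_equal(present, np.arange(1, labels.max() + 1))


class TestExtractFeatures:
    def test_square_features_analytic(self):
        labels = np.zeros((20, 20), int)
        labels[5:15, 5:15] = 1
        f = extract_features(labels, np.full((20, 20), 7.0)).iloc[0]
        assert f["num_pix"] == 100
        assert f["extend"] == 1.0
        assert f["perimeter"] == 40
        assert f["circularity"] == pytest.approx(4 * np.pi * 100 / 1600)
        assert f["mean_intensity"] == 7.0
        assert f["sd_intensity"] == 0.0

    def test_disk_extent_near_pi_over_4(self):
        from skimage.morphology import disk

        labels = np.pad(disk(20), 2).astype(int)
        f = extract_features(labels, labels.astype(float)).iloc[0]
        assert f["extend"] == pytest.approx(np.pi / 4, abs=0.05)

    def test_area_conservation(self, rng):
        mask = rng.random((50, 50)) < 0.2
        labels = label_components(mask, 8)
        f = extract_features(labels, rng.uniform(0, 1, (50, 50)))
        assert f["num_pix"].sum() == mask.sum()

    def test_translation_invariance(self):
        labels = np.zeros((40, 40), int)
        labels[5:12, 6:16] = 1
        labels[11, 6] = 0
        intens = np.zeros((40, 40))
        intens[labels == 1] = np.linspace(1, 2, (labels == 1).sum())
        f0 = extract_features(labels, intens).iloc[0]
        shifted = np.roll(np.roll(labels, 9, axis=0), 4, axis=1)
        si = np.roll(np.roll(intens, 9, axis=0), 4, axis=1)
        f1 = extract_features(shifted, si).iloc[0]
        assert f1["centroid_r"] == f0["centroid_r"] + 9
        assert f1["centroid_c"] == f0["centroid_c"] + 4
        for col in ("num_pix", "extend", "perimeter", "circularity",
                    "eccentricity", "mean_intensity", "sd_intensity"):
            assert f1[col] == pytest.approx(f0[col], rel=1e-12)

    def test_transposition_preserves_partition(self, rng):
        mask = rng.random((30, 45)) < 0.35
        a = label_components(mask, 8)
        b = label_components(mask.T, 8)
        assert partitions_equal(a, b.T)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            extract_features(np.zeros((5, 5), int), np.zeros((6, 5)))


class TestEndToEndDetection:
    def test_recall_precision_on_generator_field(self, default_field):
        """Default chain on a default-noise non-touching field: recall and
        precision of nucleus detection at least 0.95."""
        img, truth = default_field
        labels, _ = segment_field(img.channels["nuclei"])
        recall, precision = detection_scores(
            labels, truth.cells[["centroid_r", "centroid_c"]].to_numpy()
        )
        assert recall >= 0.95
        assert precision >= 0.95
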