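import numpy as np
import pytest

from sblda import CTSlice, SBLDAParams, SegmentationError
from sblda.metrics import dice
from sblda.phantom import PhantomSpec, generate_phantom, ring_mask_pixels
from sblda.postprocess import (
    invert_and_erode,
    label_components,
    largest_component,
    remove_outliers,
    ring_artifact_mask,
    segment_liver,
    select_liver,
    smooth_and_reconnect,
)
from sblda.preprocess import DisplayImage
from oracles import flood_fill_components


def _disk_image(shape, center, radius, fg=200.0, bg=1.0):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    img = np.full(shape, bg)
    img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = fg
    return img


class TestRingArtifactMask:
    def test_excludes_thin_ring_keeps_body(self):
        img = _disk_image((160, 160), (80, 80), 50)
        rr, cc = np.ogrid[:160, :160]
        d2 = (rr - 80) ** 2 + (cc - 80) ** 2
        ring = (d2 >= 57**2) & (d2 <= 59**2)
        img[ring] = 250.0
        m = ring_artifact_mask(DisplayImage(img), 20).astype(bool)
        assert ring.any() and not m[ring].any()
        assert m[80, 80] and m[60, 60]

    def test_body_mask_is_solid(self):
        # fat planes reaching the outline must not carve the body mask: M
        # covers the organs and the tissue between them
        from sblda.preprocess import apply_window

        spec = PhantomSpec(seed=2, noise_sigma=0.0)
        ct, truth = generate_phantom(spec)
        m = ring_artifact_mask(apply_window(ct, 400.0, 40.0), 20).astype(bool)
        assert m[truth.astype(bool)].all()
        assert m[128, 128]

    def test_all_foreground_gives_all_ones(self):
        img = np.full((80, 80), 200.0)
        img[0, 0] = 1.0
        assert ring_artifact_mask(DisplayImage(img), 20).all()

    def test_body_smaller_than_disk_errors(self):
        img = _disk_image((80, 80), (40, 40), 8)
        with pytest.raises(SegmentationError, match="ring_mask"):
            ring_artifact_mask(DisplayImage(img), 20)


class TestRemoveOutliers:
    def test_isolated_pixels_removed(self):
        mask = np.zeros((30, 30), dtype=np.uint8)
        mask[5, 5] = mask[20, 12] = 1
        assert remove_outliers(mask, 2).sum() == 0

    def test_solid_square_matches_skimage_oracle(self):
        from skimage.morphology import disk, opening

        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[10:30, 10:30] = 1
        out = remove_outliers(mask, 2)
        expected = (opening(mask.astype(bool), disk(2)) > 0).astype(np.uint8)
        assert np.array_equal(out, expected)
        assert out[15:25, 15:25].all()  # interior untouched

    def test_empty_mask(self):
        assert remove_outliers(np.zeros((10, 10), dtype=np.uint8), 2).sum() == 0


class TestLargestComponent:
    def test_keeps_bigger_blob(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[2:12, 2:12] = 1  # 100 px
        mask[20:25, 20:28] = 1  # 40 px
        out = largest_component(mask)
        assert out[5, 5] and not out[22, 22]

    def test_tie_breaks_leftmost(self):
        mask = np.zeros((20, 40), dtype=np.uint8)
        mask[5:10, 2:7] = 1
        mask[5:10, 30:35] = 1
        out = largest_component(mask)
        assert out[7, 4] and not out[7, 32]

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        mask = (rng.random((30, 30)) > 0.6).astype(np.uint8)
        out = largest_component(mask, connectivity=8)
        labels, sizes = flood_fill_components(mask, 8)
        biggest = max(sizes.values())
        assert out.sum() == biggest
        lbl = labels[out.astype(bool)]
        assert (lbl == lbl[0]).all() and sizes[lbl[0]] == biggest

    def test_empty_mask_errors(self):
        with pytest.raises(SegmentationError):
            largest_component(np.zeros((5, 5), dtype=np.uint8))


class TestInvertAndErode:
    def test_closed_ring_yields_separate_interior(self):
        mask = np.zeros((40, 40), dtype=np.uint8)
        mask[10, 10:31] = mask[30, 10:31] = 1
        mask[10:31, 10] = mask[10:31, 30] = 1
        mask = np.maximum(mask, np.roll(mask, 1, axis=0))  # 2 px thick
        out = invert_and_erode(mask, 2)
        labels, sizes = flood_fill_components(out.astype(bool), 8)
        assert len(sizes) >= 2  # interior disconnected from exterior
        assert labels[20, 20] != labels[2, 2] != 0

    def test_all_zero_edge_mask(self):
        out = invert_and_erode(np.zeros((20, 20), dtype=np.uint8), 2)
        assert out[5:15, 5:15].all()
        assert not out[0, :].any() and not out[:, 0].any()  # frame-shrunk

    def test_all_ones_edge_mask(self):
        assert invert_and_erode(np.ones((20, 20), dtype=np.uint8), 2).sum() == 0


class TestSmoothAndReconnect:
    def test_solid_disk_area_nearly_preserved(self):
        mask = (_disk_image((60, 60), (30, 30), 20) > 100).astype(np.uint8)
        out = smooth_and_reconnect(mask, 2.0, 5)
        assert abs(int(out.sum()) - int(mask.sum())) < 0.05 * mask.sum()

    def test_one_pixel_slit_closed(self):
        mask = (_disk_image((60, 60), (30, 30), 20) > 100).astype(np.uint8)
        mask[:, 30] = 0  # 1-px slit through the disk
        out = smooth_and_reconnect(mask, 2.0, 5)
        assert out[:, 30].any()
        _, sizes = flood_fill_components(out.astype(bool), 4)
        assert len(sizes) == 1

    def test_empty_mask(self):
        assert smooth_and_reconnect(np.zeros((20, 20), dtype=np.uint8), 2.0, 5).sum() == 0


class TestSelectLiver:
    @staticmethod
    def _labeling(*blobs, shape=(60, 100)):
        mask = np.zeros(shape, dtype=np.uint8)
        for r0, r1, c0, c1 in blobs:
            mask[r0:r1, c0:c1] = 1
        return label_components(mask), shape

    def test_large_left_beats_small_right(self):
        labeling, shape = self._labeling((10, 40, 5, 35), (10, 20, 80, 90))
        out = select_liver(labeling, shape)
        assert out[20, 20] and not out[15, 85]

    def test_left_region_rule_dominates_size(self):
        # huge right blob vs medium left blob: the anatomical rule wins
        labeling, shape = self._labeling((5, 55, 70, 99), (20, 40, 5, 25))
        out = select_liver(labeling, shape)
        assert out[30, 10] and not out[30, 85]

    def test_single_right_component_falls_back_with_warning(self):
        labeling, shape = self._labeling((10, 30, 80, 95))
        with pytest.warns(UserWarning, match="left region"):
            out = select_liver(labeling, shape)
        assert out[20, 85]

    def test_no_components_errors(self):
        labeling = label_components(np.zeros((10, 10), dtype=np.uint8))
        with pytest.raises(SegmentationError):
            select_liver(labeling, (10, 10))


class TestSegmentLiver:
    def test_clean_phantom_recovery(self, clean_phantom):
        ct, truth = clean_phantom
        mask = segment_liver(ct)
        assert dice(mask, truth) >= 0.95

    def test_deterministic_bit_exact(self, clean_phantom):
        ct, _ = clean_phantom
        assert np.array_equal(segment_liver(ct), segment_liver(ct))

    def test_final_mask_single_component(self, clean_phantom):
        ct, _ = clean_phantom
        mask = segment_liver(ct)
        _, sizes = flood_fill_components(mask.astype(bool), 8)
        assert len(sizes) == 1

    def test_constant_image_fails_at_confidence_stage(self):
        ct = CTSlice(np.full((60, 60), 40.0))
        with pytest.raises(SegmentationError, match="confidence"):
            segment_liver(ct)

    def test_ring_artifact_excluded(self):
        spec = PhantomSpec(seed=2, noise_sigma=0.0, ring=True)
        ct, truth = generate_phantom(spec)
        mask = segment_liver(ct)
        assert dice(mask, truth) >= 0.95
        assert not (mask.astype(bool) & ring_mask_pixels(spec)).any()

    def test_body_mask_never_adds_candidates(self, clean_phantom):
        # M acts by intersection: candidates with M are a subset of the
        # interior regions without it
        ct, _ = clean_phantom
        inter = {}
        segment_liver(ct, intermediates=inter)
        cand = inter["candidates"].astype(bool)
        regions = inter["interior_regions"].astype(bool)
        assert (cand <= regions).all() and cand.sum() < regions.sum()

    def test_dice_trend_degrades_with_noise(self):
        # mean Dice over 5 fixed seeds: flat (within slack) at moderate
        # noise, clearly degraded at heavy noise
        sigmas = (0.0, 20.0, 120.0)
        means = []
        for sigma in sigmas:
            scores = []
            for s in range(5):
                ct, truth = generate_phantom(PhantomSpec(seed=100 + s, noise_sigma=sigma))
                try:
                    scores.append(dice(segment_liver(ct), truth))
                except SegmentationError:
                    scores.append(0.0)
            means.append(np.mean(scores))
        for a, b in zip(means, means[1:]):
            assert b <= a + 0.01
        assert means[-1] < means[0] - 0.05
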