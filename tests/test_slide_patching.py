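import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normatlas import (
    ABNORMAL,
    NORMAL,
    PatchGridConfig,
    PatchRecord,
    SlideMeta,
    TissueMask,
    compute_tissue_mask,
    extract_patch_images,
    filter_by_tissue,
    generate_patch_grid,
    label_patches_from_annotation,
)


def brute_force_grid(width, height, patch_size, stride):
    """Independent oracle: enumerate all fully contained origins."""
    out = []
    y = 0
    while y + patch_size <= height:
        x = 0
        while x + patch_size <= width:
            out.append((x, y))
            x += stride
        y += stride
    return out


class TestPatchGrid:
    @pytest.mark.parametrize(
        "width,height,expected_n",
        [(1024, 1024, 1), (4096, 4096, 25), (1000, 4096, 0), (0, 0, 0)],
    )
    def test_grid_counts(self, width, height, expected_n):
        cfg = PatchGridConfig()
        grid = generate_patch_grid(width, height, cfg)
        assert len(grid) == expected_n

    def test_stride_and_last_origin_for_default_parameters(self):
        cfg = PatchGridConfig(patch_size=1024, overlap=0.30)
        assert cfg.stride == 716
        grid = generate_patch_grid(4096, 4096, cfg)
        assert grid[-1].x == 2864 and grid[-1].y == 2864
        # row-major: y outer, x inner
        assert [(p.x, p.y) for p in grid[:5]] == [(0, 0), (716, 0), (1432, 0), (2148, 0), (2864, 0)]

    def test_grid_matches_brute_force_enumeration(self, rng):
        for _ in range(200):
            patch = int(rng.integers(1, 600))
            overlap = float(rng.uniform(0, 0.95))
            cfg_stride = math.floor(patch * (1 - overlap))
            if cfg_stride < 1:
                continue
            cfg = PatchGridConfig(patch_size=patch, overlap=overlap, min_tissue=0.5)
            width = int(rng.integers(0, 3000))
            height = int(rng.integers(0, 3000))
            grid = [(p.x, p.y) for p in generate_patch_grid(width, height, cfg)]
            assert grid == brute_force_grid(width, height, patch, cfg.stride)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        width=st.integers(0, 5000),
        height=st.integers(0, 5000),
        patch=st.integers(1, 1200),
        overlap=st.floats(0, 0.9),
    )
    def test_grid_containment_and_uniqueness(self, width, height, patch, overlap):
        if math.floor(patch * (1 - overlap)) < 1:
            return
        cfg = PatchGridConfig(patch_size=patch, overlap=overlap)
        grid = generate_patch_grid(width, height, cfg)
        coords = [(p.x, p.y) for p in grid]
        assert len(set(coords)) == len(coords)
        for p in grid:
            assert p.x >= 0 and p.y >= 0
            assert p.x + p.size <= width and p.y + p.size <= height


class TestTissueMask:
    def test_pure_white_image_has_no_tissue(self):
        image = np.full((512, 512, 3), 255, dtype=np.uint8)
        mask = compute_tissue_mask(image, downscale=1.0)
        assert mask.array.sum() == 0

    def test_pink_square_area_recovered(self):
        image = np.full((512, 512, 3), 255, dtype=np.uint8)
        image[100:356, 100:356] = (226, 150, 190)
        downscale = 0.5
        mask = compute_tissue_mask(image, downscale=downscale)
        expected = 256**2 * downscale**2
        assert abs(mask.array.sum() - expected) <= 0.05 * expected

    def test_mask_dimensions_follow_ceil_rule(self):
        image = np.full((101, 77, 3), 255, dtype=np.uint8)
        mask = compute_tissue_mask(image, downscale=0.3)
        assert mask.array.shape == (math.ceil(101 * 0.3), math.ceil(77 * 0.3))

    def test_jaccard_against_planted_truth(self, small_slide):
        from skimage.transform import resize

        image, tissue_truth, _, meta = small_slide
        mask = compute_tissue_mask(image, downscale=0.25, wsi_id=meta.wsi_id)
        truth = resize(tissue_truth.astype(float), mask.array.shape, anti_aliasing=False) > 0.5
        inter = (mask.array & truth).sum()
        union = (mask.array | truth).sum()
        assert inter / union >= 0.8

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_tissue_mask(np.empty((0, 0, 3)), 1.0)
        with pytest.raises(ValueError):
            compute_tissue_mask(np.zeros((10, 10)), 1.0)
        with pytest.raises(ValueError):
            compute_tissue_mask(np.zeros((10, 10, 3), dtype=np.uint8), 0.0)


def _patches(coords, size, wsi_id="w"):
    return [PatchRecord(wsi_id=wsi_id, x=x, y=y, size=size) for x, y in coords]


class TestTissueFilter:
    def test_all_ones_mask_retains_everything(self):
        mask = TissueMask(np.ones((200, 200)), 1.0, "w")
        patches = _patches([(0, 0), (50, 50), (100, 100)], 100)
        kept = filter_by_tissue(patches, mask, 0.75)
        assert kept == patches
        assert all(p.tissue_fraction == 1.0 for p in patches)

    def test_all_zeros_mask_retains_nothing(self):
        mask = TissueMask(np.zeros((200, 200)), 1.0, "w")
        patches = _patches([(0, 0), (100, 100)], 100)
        assert filter_by_tissue(patches, mask, 0.75) == []
        assert all(p.tissue_fraction == 0.0 for p in patches)

    def test_half_coverage_boundary_is_inclusive(self):
        arr = np.zeros((100, 200))
        arr[:, :100] = 1  # left half is tissue
        mask = TissueMask(arr, 1.0, "w")
        straddling = _patches([(50, 0)], 100)
        assert filter_by_tissue(straddling, mask, 0.75) == []
        assert straddling[0].tissue_fraction == pytest.approx(0.5)
        assert filter_by_tissue(straddling, mask, 0.5) == straddling

    def test_filter_is_idempotent_and_monotone(self, rng):
        arr = rng.random((128, 128)) > 0.4
        mask = TissueMask(arr, 0.5, "w")
        patches = _patches([(0, 0), (64, 64), (128, 128), (32, 96)], 64)
        kept_50 = filter_by_tissue(patches, mask, 0.5)
        assert filter_by_tissue(list(kept_50), mask, 0.5) == kept_50
        kept_80 = filter_by_tissue(patches, mask, 0.8)
        assert set((p.x, p.y) for p in kept_80) <= set((p.x, p.y) for p in kept_50)

    def test_wsi_mismatch_rejected(self):
        mask = TissueMask(np.ones((10, 10)), 1.0, "other")
        with pytest.raises(ValueError, match="other"):
            filter_by_tissue(_patches([(0, 0)], 10, wsi_id="w"), mask, 0.5)


class TestAnnotationLabeling:
    def test_exact_half_overlap_is_abnormal_49_percent_is_normal(self):
        ann = np.zeros((100, 300))
        ann[:, 0:49] = 1  # 49% of the first patch
        ann[:, 100:151] = 1  # 51% of the second
        mask = TissueMask(ann, 1.0, "w")
        patches = _patches([(0, 0), (100, 0), (200, 0)], 100)
        labeled = label_patches_from_annotation(patches, mask, threshold=0.5)
        assert [p.gt_label for p in labeled] == [NORMAL, ABNORMAL, NORMAL]

        exact = np.zeros((100, 100))
        exact[:, :50] = 1  # exactly 50%: inclusive boundary
        half = label_patches_from_annotation(_patches([(0, 0)], 100), TissueMask(exact, 1.0, "w"))
        assert half[0].gt_label == ABNORMAL

    def test_all_zero_annotation_labels_everything_normal(self):
        mask = TissueMask(np.zeros((100, 100)), 1.0, "w")
        labeled = label_patches_from_annotation(_patches([(0, 0)], 100), mask)
        assert all(p.gt_label == NORMAL for p in labeled)

    def test_threshold_extremes(self):
        ann = np.zeros((100, 100))
        ann[0, 0] = 1
        mask = TissueMask(ann, 1.0, "w")
        patches = _patches([(0, 0)], 100)
        assert label_patches_from_annotation(patches, mask, 0.0)[0].gt_label == ABNORMAL
        assert label_patches_from_annotation(patches, mask, 1.0)[0].gt_label == NORMAL
        full = TissueMask(np.ones((100, 100)), 1.0, "w")
        assert label_patches_from_annotation(patches, full, 1.0)[0].gt_label == ABNORMAL

    def test_missing_annotation_is_an_error(self):
        with pytest.raises(ValueError):
            label_patches_from_annotation(_patches([(0, 0)], 10), None)


class TestPatchExtraction:
    def _meta(self, w, h):
        return SlideMeta("w", "p", "normal", w, h, 20.0)

    def test_identity_crop(self, rng):
        image = rng.integers(0, 255, (64, 64, 3), dtype=np.uint8)
        crops = list(extract_patch_images(self._meta(64, 64), _patches([(0, 0)], 64), image=image))
        assert len(crops) == 1 and np.array_equal(crops[0], image)

    def test_crop_matches_direct_slice(self):
        ramp = np.arange(40 * 40 * 3, dtype=np.uint8).reshape(40, 40, 3)
        crops = list(extract_patch_images(self._meta(40, 40), _patches([(10, 20)], 4), image=ramp))
        assert np.array_equal(crops[0], ramp[20:24, 10:14])

    def test_empty_patch_list_yields_nothing(self):
        assert list(extract_patch_images(self._meta(10, 10), [], image=np.zeros((10, 10, 3)))) == []

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            list(
                extract_patch_images(
                    self._meta(32, 32), _patches([(20, 20)], 16), image=np.zeros((32, 32, 3))
                )
            )

    def test_missing_magnification_rejected(self):
        with pytest.raises(ValueError, match="magnification"):
            SlideMeta("w", "p", "normal", 10, 10, 0.0)
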