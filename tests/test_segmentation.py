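"""Classical segmenter: tissue/background separation, fat recovery, artifact rejection."""
import numpy as np
import pytest
from conftest import BRIGHT, iou, paint_disc, pink_image, white_image

import steatoquant as sq
from steatoquant.segmentation import bright_pixel_map, classical_backend, segment_tiles
from steatoquant.tiling import stitch_masks, tile_image


def test_uniform_near_white_image_has_no_tissue():
    img = sq.FieldImage(white_image(128, 128))
    assert sq.compute_tissue_mask(img).count == 0


def test_uniform_pink_image_is_all_tissue_no_fat():
    img = sq.FieldImage(pink_image(128, 128))
    assert sq.compute_tissue_mask(img).count == 128 * 128
    assert sq.segment_classical(img).count == 0


def test_tissue_mask_matches_ground_truth():
    agreements = []
    for seed in range(10):
        spec = sq.SyntheticSlideSpec(256, 256, target_fat_fraction=0.2, seed=seed)
        img, truth = sq.generate_field(spec)
        tissue = sq.compute_tissue_mask(img)
        agreements.append(
            np.count_nonzero(tissue.values == truth.tissue_mask.values) / tissue.values.size
        )
    assert min(agreements) >= 0.99


def test_fat_mask_subset_of_tissue_mask(small_field):
    img, _ = small_field
    fat = sq.segment_classical(img)
    tissue = sq.compute_tissue_mask(img)
    assert fat.is_subset_of(tissue)


def test_lowering_luminance_threshold_never_shrinks_candidates():
    rng = np.random.default_rng(0)
    for _ in range(5):
        img = sq.FieldImage(rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8))
        loose = bright_pixel_map(img, sq.SegmenterConfig(tau_L=0.60))
        tight = bright_pixel_map(img, sq.SegmenterConfig(tau_L=0.90))
        assert not np.any(tight & ~loose)


def _tear_and_vacuole_fixture():
    """Pink field with one thin horizontal tear and three discs of known shape."""
    arr = pink_image(512, 512)
    tear = np.zeros((512, 512), bool)
    tear[250:256, 100:400] = True  # 6 x 300 bar: circularity ~ 4*pi*A/P^2 << 0.2
    arr[tear] = BRIGHT
    vacuoles = np.zeros((512, 512), bool)
    for cy, cx in ((100, 100), (120, 380), (400, 250)):
        vacuoles |= paint_disc(arr, cy, cx, 12)
    return sq.FieldImage(arr), tear, vacuoles


def test_tear_rejected_vacuoles_retained():
    img, tear, vacuoles = _tear_and_vacuole_fixture()
    fat = sq.segment_classical(img)
    assert np.count_nonzero(fat.values & tear) == 0
    retained = np.count_nonzero(fat.values & vacuoles) / np.count_nonzero(vacuoles)
    assert retained >= 0.95


def test_tear_and_vacuole_circularities_straddle_the_filter():
    img, tear, vacuoles = _tear_and_vacuole_fixture()
    vs = sq.label_vacuoles(np.asarray(tear))
    assert vs.vacuoles[0].circularity < 0.2
    disc_set = sq.label_vacuoles(vacuoles)
    assert all(v.circularity > 0.7 for v in disc_set.vacuoles)


def test_ground_truth_recovery_on_artifact_free_field():
    spec = sq.SyntheticSlideSpec(512, 512, target_fat_fraction=0.25, seed=21)
    img, truth = sq.generate_field(spec)
    fat = sq.segment_classical(img)
    tissue = sq.compute_tissue_mask(img)
    est = fat.count / tissue.count
    assert abs(est - truth.achieved_fat_fraction) <= 0.02
    assert iou(fat.values, truth.fat_mask.values) >= 0.85


def test_segment_tiles_validates_backend_contract():
    img = sq.FieldImage(pink_image(256, 256))
    grid = tile_image(img, 128, "drop_partial")
    tiles = [sq.FieldImage(t) for t in grid.extract(img)]

    def bad_shape_backend(tile):
        return np.zeros((64, 64), bool)

    with pytest.raises(sq.ContractError, match="tile 0"):
        segment_tiles(grid, tiles, bad_shape_backend)

    def non_binary_backend(tile):
        return np.full(tile.shape, 2, dtype=np.int64)

    with pytest.raises(sq.ContractError, match="tile 0"):
        segment_tiles(grid, tiles, non_binary_backend)


def test_constant_pink_tiles_give_all_zero_masks():
    img = sq.FieldImage(pink_image(256, 256))
    grid = tile_image(img, 128, "drop_partial")
    tiles = [sq.FieldImage(t) for t in grid.extract(img)]
    masks = segment_tiles(grid, tiles, classical_backend(per_tile=True))
    assert all(m.count == 0 for m in masks)


def test_threshold_stub_backend_equals_global_threshold_map(small_field):
    img, _ = small_field
    cfg = sq.SegmenterConfig()

    def stub(tile):
        return tile.luminance() >= cfg.tau_L

    grid = tile_image(img, 64, "drop_partial")
    tiles = [sq.FieldImage(t) for t in grid.extract(img)]
    masks = segment_tiles(grid, tiles, stub)
    stitched = stitch_masks(grid, masks)
    global_map = img.luminance() >= cfg.tau_L
    cov = grid.coverage_mask()
    assert np.array_equal(stitched.values[cov], global_map[cov])


def test_tile_interior_vacuole_segments_like_whole_image():
    arr = pink_image(512, 512)
    paint_disc(arr, 320, 320, 14)  # fully inside the 256-px tile (1, 1)
    img = sq.FieldImage(arr)
    whole = sq.segment_classical(img)
    grid = tile_image(img, 256, "drop_partial")
    tiles = [sq.FieldImage(t) for t in grid.extract(img)]
    masks = segment_tiles(grid, tiles, classical_backend(per_tile=True))
    stitched = stitch_masks(grid, masks)
    assert np.array_equal(stitched.values, whole.values)
    assert whole.count > 0
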