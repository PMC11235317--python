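"""Field sampling, Pearson correlation, heterogeneity index, comparison experiment."""
import math

import numpy as np
import pytest

import steatoquant as sq
from steatoquant.validation import _slide_spec, heterogeneity_index, pearson_r, sample_fields


def test_pearson_perfect_correlations():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pearson_r(x, x) == pytest.approx(1.0)
    assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)


def test_pearson_against_longhand_formula():
    x = (1.0, 2.0, 3.0, 4.0)
    y = (1.0, 3.0, 2.0, 5.0)
    # longhand: cov = 5.5, ss_x = 5, ss_y = 8.75
    expected = 5.5 / math.sqrt(5.0 * 8.75)
    assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_undefined_cases_raise():
    with pytest.raises(sq.ContractError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(sq.ContractError):
        pearson_r([1.0, 2.0], [1.0, 2.0])


def test_pearson_symmetry_and_affine_invariance():
    rng = np.random.default_rng(0)
    x = rng.random(20)
    y = rng.random(20)
    assert pearson_r(x, y) == pytest.approx(pearson_r(y, x))
    assert pearson_r(2.5 * x + 1.0, y) == pytest.approx(pearson_r(x, y))


def _slide_image(h=400, w=600, seed=0):
    img, truth = sq.generate_slide(
        sq.SyntheticSlideSpec(w, h, target_fat_fraction=0.2, seed=seed, max_attempts=100_000)
    )
    return img, truth


def test_sampled_fields_pairwise_disjoint_by_bruteforce():
    img, _ = _slide_image()
    fields = sample_fields(img, k=3, field_h=100, field_w=150, seed=5)
    offsets = [off for _, off in fields]
    for i in range(len(offsets)):
        for j in range(i + 1, len(offsets)):
            (y1, x1), (y2, x2) = offsets[i], offsets[j]
            overlap_y = max(0, min(y1 + 100, y2 + 100) - max(y1, y2))
            overlap_x = max(0, min(x1 + 150, x2 + 150) - max(x1, x2))
            assert overlap_y * overlap_x == 0


def test_sampling_is_deterministic_under_seed():
    img, _ = _slide_image()
    a = [off for _, off in sample_fields(img, 3, 100, 150, seed=9)]
    b = [off for _, off in sample_fields(img, 3, 100, 150, seed=9)]
    assert a == b


def test_slide_sized_field_returns_whole_slide():
    img, _ = _slide_image(h=200, w=300, seed=1)
    fields = sample_fields(img, k=1, field_h=200, field_w=300, seed=0)
    (field, offset), = fields
    assert offset == (0, 0)
    assert np.array_equal(field.pixels, img.pixels)


def test_infeasible_k_raises_with_capacity():
    img, _ = _slide_image(h=200, w=300, seed=1)
    with pytest.raises(sq.SamplingError, match="maximum feasible k"):
        sample_fields(img, k=50, field_h=100, field_w=150, seed=0, max_attempts=2000)


def test_heterogeneity_index_zero_for_replicated_pattern():
    fat = np.zeros((128, 128), bool)
    fat[8:20, 8:20] = True
    fat = np.tile(fat[:32, :32], (4, 4))  # identical 32-px blocks
    tissue = np.ones((128, 128), bool)
    idx = heterogeneity_index(sq.BinaryMask(fat, "fat"), sq.BinaryMask(tissue, "tissue"), 32)
    assert idx == 0.0


def test_heterogeneity_index_one_hot_closed_form():
    # all fat concentrated in one of n = 6 blocks -> CV = sqrt(n - 1)
    fat = np.zeros((64, 96), bool)
    fat[2:10, 2:10] = True
    tissue = np.ones((64, 96), bool)
    idx = heterogeneity_index(sq.BinaryMask(fat, "fat"), sq.BinaryMask(tissue, "tissue"), 32)
    assert idx == pytest.approx(math.sqrt(6 - 1))


def test_heterogeneity_index_error_cases():
    fat = sq.BinaryMask(np.zeros((64, 64), bool), "fat")
    no_tissue = sq.BinaryMask(np.zeros((64, 64), bool), "tissue")
    with pytest.raises(sq.ContractError):
        heterogeneity_index(fat, no_tissue, 32)
    with pytest.raises(sq.ContractError):
        heterogeneity_index(fat, no_tissue, 4)
    all_tissue = sq.BinaryMask(np.ones((64, 64), bool), "tissue")
    assert heterogeneity_index(fat, all_tissue, 32) == 0.0


def test_clustered_slides_have_larger_heterogeneity_index():
    uniform, clustered = [], []
    for seed in range(20):
        for het, out in ((0.0, uniform), (5.0, clustered)):
            spec = sq.SyntheticSlideSpec(
                384, 256, target_fat_fraction=0.2, heterogeneity=het, seed=seed,
                max_attempts=100_000,
            )
            _, truth = sq.generate_slide(spec)
            out.append(heterogeneity_index(truth.fat_mask, truth.tissue_mask, 64))
    assert np.mean(clustered) > np.mean(uniform)


def test_exhaustive_coverage_matches_wholeslide_score():
    """A single field covering the whole mosaic reproduces the whole-slide score."""
    cfg = sq.RunConfig(tile_size=96)
    img, _ = sq.generate_slide(
        sq.SyntheticSlideSpec(288, 192, target_fat_fraction=0.25, seed=2)
    )
    whole = sq.quantify_field(img, cfg.with_updates(tile_policy="pad_reflect"))
    (field, _), = sample_fields(img, 1, 192, 288, seed=0)
    device = sq.quantify_slide([field], cfg)
    assert abs(device.slide_fraction - whole.fraction) <= 0.01


def test_run_comparison_consistent_and_deterministic():
    kwargs = dict(
        n_slides=3, fat_fraction_range=(0.05, 0.4), heterogeneity=0.0, k=2, seed=7,
        config=sq.RunConfig(tile_size=96), slide_height=384, slide_width=576,
        field_height=128, field_width=192, het_window=96,
    )
    result = sq.run_comparison(**kwargs)
    assert result.n_slides == 3
    xs = [s.wholeslide_fraction for s in result.per_slide]
    ys = [s.device_fraction for s in result.per_slide]
    assert result.pearson_r == pytest.approx(pearson_r(xs, ys))
    for s in result.per_slide:
        assert s.abs_deviation == pytest.approx(abs(s.device_fraction - s.wholeslide_fraction))
        assert -1.0 <= result.pearson_r <= 1.0
    again = sq.run_comparison(**kwargs)
    assert again.pearson_r == result.pearson_r
    assert again.to_dataframe().equals(result.to_dataframe())


def test_run_comparison_requires_three_slides():
    with pytest.raises(sq.ContractError):
        sq.run_comparison(n_slides=2)


def test_slide_spec_scales_attempt_cap_with_area():
    small = _slide_spec(0.3, 0.0, 1, 256, 256)
    large = _slide_spec(0.3, 0.0, 1, 2048, 2048)
    assert large.max_attempts > small.max_attempts >= 10_000
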