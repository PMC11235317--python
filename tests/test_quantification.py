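"""Percent-steatosis arithmetic, the field pipeline, stability filtering, slide averaging."""
import numpy as np
import pytest
from conftest import brute_force_fraction, pink_image, white_image
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import steatoquant as sq
from steatoquant.quantification import sharpness_score


def _mask(arr, semantics):
    return sq.BinaryMask(np.asarray(arr, dtype=bool), semantics)


def test_percent_steatosis_exact_arithmetic():
    tissue = np.zeros((100, 100), bool)
    tissue[:100, :100] = True
    fat = np.zeros((100, 100), bool)
    est = sq.percent_steatosis(_mask(fat, "fat"), _mask(tissue, "tissue"))
    assert est.fraction == 0.0
    fat[:25, :100] = True  # 2500 of 10000
    est = sq.percent_steatosis(_mask(fat, "fat"), _mask(tissue, "tissue"))
    assert est.fraction == 0.25
    assert est.fat_px == 2500 and est.tissue_px == 10000


@settings(derandomize=True, max_examples=100, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_percent_steatosis_equals_bruteforce_pixel_count(seed):
    rng = np.random.default_rng(seed)
    tissue = rng.random((24, 18)) < 0.8
    if not tissue.any():
        tissue[0, 0] = True
    fat = (rng.random((24, 18)) < 0.3) & tissue
    est = sq.percent_steatosis(_mask(fat, "fat"), _mask(tissue, "tissue"))
    fat_px, tissue_px = brute_force_fraction(fat, tissue)
    assert est.fat_px == fat_px
    assert est.tissue_px == tissue_px
    assert est.fraction == fat_px / tissue_px


def test_fat_outside_tissue_is_a_contract_error():
    fat = np.ones((10, 10), bool)
    tissue = np.zeros((10, 10), bool)
    tissue[:5] = True
    with pytest.raises(sq.ContractError):
        sq.percent_steatosis(_mask(fat, "fat"), _mask(tissue, "tissue"))


def test_empty_tissue_raises_no_tissue_error():
    empty = np.zeros((10, 10), bool)
    with pytest.raises(sq.NoTissueError):
        sq.percent_steatosis(_mask(empty, "fat"), _mask(empty, "tissue"))


def test_fraction_one_only_when_fat_equals_tissue():
    tissue = np.zeros((10, 10), bool)
    tissue[2:8, 2:8] = True
    est = sq.percent_steatosis(_mask(tissue.copy(), "fat"), _mask(tissue, "tissue"))
    assert est.fraction == 1.0


def test_field_fraction_equals_per_tile_pooled_counts(small_field):
    img, truth = small_field
    cfg = sq.RunConfig(tile_size=64)
    est = sq.quantify_field(img, cfg)
    included = [t for t in est.per_tile if t.included]
    assert est.fat_px == sum(t.fat_px for t in included)
    assert est.tissue_px == sum(t.tissue_px for t in included)
    assert est.fraction == est.fat_px / est.tissue_px
    assert abs(est.fraction - truth.achieved_fat_fraction) <= 0.02


def test_all_background_field_has_no_tissue():
    img = sq.FieldImage(white_image(256, 256))
    with pytest.raises(sq.NoTissueError):
        sq.quantify_field(img, sq.RunConfig(tile_size=64))


def test_constant_image_scores_zero_sharpness_and_is_rejected():
    img = sq.FieldImage(pink_image(64, 64))
    assert sharpness_score(img) == 0.0
    accepted, rejected = sq.stability_filter([img], tau_F=0.001)
    assert accepted == []
    assert rejected == [(img.source_id, "unsharp")]


def test_blur_lowers_sharpness_below_separating_threshold(small_field):
    img, _ = small_field
    blurred_px = ndimage.gaussian_filter(img.pixels.astype(float), sigma=(3, 3, 0))
    blurred = sq.FieldImage(np.clip(blurred_px, 0, 255).astype(np.uint8), source_id="blurred")
    s_orig, s_blur = sharpness_score(img), sharpness_score(blurred)
    assert s_orig > s_blur
    tau = (s_orig + s_blur) / 2
    accepted, rejected = sq.stability_filter([img, blurred], tau_F=tau)
    assert [a.source_id for a in accepted] == [img.source_id]
    assert rejected == [("blurred", "unsharp")]


def test_sharp_synthetic_field_passes_default_filter(small_field):
    img, _ = small_field
    accepted, rejected = sq.stability_filter([img])
    assert rejected == [] and len(accepted) == 1


def test_nearly_tissue_free_field_rejected():
    arr = white_image(256, 256)
    rng = np.random.default_rng(0)
    arr = np.clip(arr.astype(int) + rng.integers(-6, 6, arr.shape), 0, 255).astype(np.uint8)
    img = sq.FieldImage(arr, source_id="empty")
    _, rejected = sq.stability_filter([img], tau_F=0.0)
    assert rejected == [("empty", "insufficient tissue")]


def _three_fields():
    fields = []
    for seed, target in ((1, 0.05), (2, 0.20), (3, 0.35)):
        img, _ = sq.generate_field(
            sq.SyntheticSlideSpec(256, 256, target_fat_fraction=target, seed=seed)
        )
        fields.append(sq.FieldImage(img.pixels, source_id=f"f{seed}"))
    return fields


def test_slide_fraction_is_mean_of_field_fractions_and_permutation_invariant():
    cfg = sq.RunConfig(tile_size=64)
    fields = _three_fields()
    est = sq.quantify_slide(fields, cfg)
    assert est.valid and est.n_fields == 3
    fractions = [e.fraction for e in est.field_estimates]
    assert est.slide_fraction == pytest.approx(np.mean(fractions), abs=1e-12)
    shuffled = sq.quantify_slide(fields[::-1], cfg)
    assert shuffled.slide_fraction == pytest.approx(est.slide_fraction, abs=1e-12)


def test_single_accepted_field_sets_the_slide_fraction():
    cfg = sq.RunConfig(tile_size=64)
    field = _three_fields()[1]
    est = sq.quantify_slide([field], cfg)
    assert est.slide_fraction == est.field_estimates[0].fraction


def test_adding_fat_free_field_never_increases_slide_fraction():
    cfg = sq.RunConfig(tile_size=64)
    fatty, _ = sq.generate_field(sq.SyntheticSlideSpec(256, 256, target_fat_fraction=0.3, seed=4))
    lean, _ = sq.generate_field(sq.SyntheticSlideSpec(256, 256, target_fat_fraction=0.0, seed=5))
    alone = sq.quantify_slide([fatty], cfg)
    combined = sq.quantify_slide([fatty, lean], cfg)
    assert combined.slide_fraction <= alone.slide_fraction


def test_all_fields_rejected_yields_invalid_estimate():
    imgs = [sq.FieldImage(pink_image(64, 64), source_id=f"c{i}") for i in range(2)]
    est = sq.quantify_slide(imgs, sq.RunConfig(tile_size=64))
    assert not est.valid
    assert est.slide_fraction is None
    assert est.invalid_reason == "all fields rejected"
    assert {r[1] for r in est.rejected_fields} == {"unsharp"}


def test_empty_image_list_is_an_error():
    with pytest.raises(sq.ContractError):
        sq.stability_filter([])
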