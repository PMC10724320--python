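"""Granule size/pattern/category classification and detection tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hifquant.fusion import FusedImage, fuse_stack
from hifquant.granules import (
    Granule,
    GranuleSizeThresholds,
    NucleusRecord,
    SizeClass,
    classify_granule_size,
    classify_nucleus_pattern,
    detect_granules,
    detect_nuclei,
    pattern_to_category,
    score_fused_image,
    specimen_immunoreactivity,
)
from hifquant.synthetic import (
    FieldTruth,
    GranuleTruth,
    NucleusTruth,
    NUCLEUS_RGB,
    BACKGROUND_RGB,
    generate_specimen_stack,
    hif1a_cohort_spec,
    render_stack,
)

from conftest import iou_match


# --------------------------------------------------------------------------
# size classes
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "diameter, expected",
    [
        (1.19, SizeClass.SUB_THRESHOLD),
        (1.2, SizeClass.SMALL),
        (1.4, SizeClass.SMALL),
        (1.6, SizeClass.SMALL),
        (1.601, SizeClass.LARGE),
        (2.2, SizeClass.LARGE),
        (2.201, SizeClass.OVER_RANGE),
        (2.5, SizeClass.OVER_RANGE),
        (0.3, SizeClass.SUB_THRESHOLD),
    ],
)
def test_size_class_boundaries(diameter, expected):
    assert classify_granule_size(diameter) is expected


def test_nonpositive_diameter_rejected():
    with pytest.raises(ValueError):
        classify_granule_size(0.0)
    with pytest.raises(ValueError):
        classify_granule_size(-1.0)


def test_threshold_validation():
    with pytest.raises(ValueError):
        GranuleSizeThresholds(small_min=1.6, small_max=1.2, large_max=2.2)


# --------------------------------------------------------------------------
# pattern + category rules vs brute-force enumeration
# --------------------------------------------------------------------------


def _granule(size_class: SizeClass) -> Granule:
    d = {"small": 1.4, "large": 2.0, "sub_threshold": 0.8, "over_range": 3.0}[size_class.value]
    return Granule(center=(0.0, 0.0), area_px=10, equivalent_diameter_um=d, size_class=size_class)


def rule_table_pattern(n_small: int, n_large: int, few_max: int) -> int:
    """Independent enumeration oracle for the five-way pattern taxonomy."""
    if n_large >= 1:
        if n_large <= few_max:
            return 3
        return 4
    if n_small >= 1:
        if n_small <= few_max:
            return 1
        return 2
    return 5


@pytest.mark.parametrize("few_max", [1, 4, 7])
def test_pattern_matches_enumeration_oracle(few_max):
    for n_small in range(11):
        for n_large in range(11):
            granules = [_granule(SizeClass.SMALL)] * n_small
            granules += [_granule(SizeClass.LARGE)] * n_large
            # out-of-range granules must never influence the pattern
            granules += [_granule(SizeClass.SUB_THRESHOLD), _granule(SizeClass.OVER_RANGE)]
            assert classify_nucleus_pattern(granules, few_max) == rule_table_pattern(
                n_small, n_large, few_max
            )


def test_pattern_examples():
    assert classify_nucleus_pattern([]) == 5
    assert classify_nucleus_pattern([_granule(SizeClass.SMALL)] * 2, few_max=4) == 1
    assert classify_nucleus_pattern([_granule(SizeClass.SMALL)] * 7, few_max=4) == 2


@pytest.mark.parametrize("pattern, category", [(5, 1), (1, 1), (2, 2), (3, 3), (4, 4)])
def test_pattern_to_category(pattern, category):
    assert pattern_to_category(pattern) == category


def test_invalid_pattern_rejected():
    with pytest.raises(ValueError):
        pattern_to_category(0)
    with pytest.raises(ValueError):
        pattern_to_category(6)


# --------------------------------------------------------------------------
# specimen summaries
# --------------------------------------------------------------------------


def _record(category: int, goblet: bool = False) -> NucleusRecord:
    pattern = {1: 1, 2: 2, 3: 3, 4: 4}[category]
    r = NucleusRecord(id=0, goblet=goblet)
    if not goblet:
        r.pattern, r.category = pattern, category
    return r


def test_specimen_positivity_examples():
    recs = [_record(c) for c in (1, 2, 3, 4, 1)]
    assert specimen_immunoreactivity(recs).positivity == 60.0
    assert specimen_immunoreactivity([_record(1)] * 4).positivity == 0.0


def test_goblet_records_excluded_from_both_counts():
    recs = [_record(4), _record(1), _record(2, goblet=True)]
    s = specimen_immunoreactivity(recs)
    assert (s.n_counted, s.n_positive) == (2, 1)
    assert s.positivity == 50.0


def test_all_goblet_raises():
    with pytest.raises(ValueError):
        specimen_immunoreactivity([_record(1, goblet=True)])


def test_specimen_percent_uses_half_up_integer_rounding():
    recs = [_record(4)] * 28 + [_record(1)] * 27
    assert specimen_immunoreactivity(recs).positivity_pct == 51


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.integers(min_value=1, max_value=4), min_size=1, max_size=30))
def test_adding_positive_nucleus_never_decreases_positivity(categories):
    recs = [_record(c) for c in categories]
    before = specimen_immunoreactivity(recs).positivity
    after = specimen_immunoreactivity(recs + [_record(4)]).positivity
    assert after >= before


# --------------------------------------------------------------------------
# detection on rendered fields
# --------------------------------------------------------------------------


def test_blank_image_yields_no_nuclei():
    blank = np.full((64, 64, 3), 235, dtype=np.uint8)
    assert detect_nuclei(FusedImage(image=blank, um_per_pixel=0.25)) == []


def test_detected_nuclei_match_truth_masks(tiny_spec):
    stack, truth = generate_specimen_stack(tiny_spec, 7)
    fused = fuse_stack(stack)
    masks = detect_nuclei(fused)
    non_goblet = [n for n in truth.nuclei if not n.goblet]
    assert len(masks) == len(non_goblet)
    for n in non_goblet:
        _, iou = iou_match(n.mask(fused.image.shape[:2], tiny_spec.um_per_pixel), masks)
        assert iou >= 0.5


def _manual_field(nuclei, spec):
    truth = FieldTruth(nuclei=nuclei, target_positivity=0.0, positivity=0.0)
    return render_stack(truth, spec, np.random.default_rng(0)), truth


def test_touching_nuclei_are_split_by_watershed(tiny_spec):
    spec = tiny_spec
    r_px = 4.5 / spec.um_per_pixel
    nuclei = [
        NucleusTruth(center_px=(96.0, 60.0), radius_um=4.5, goblet=False,
                     granules=[], pattern=5, category=1),
        NucleusTruth(center_px=(96.0, 60.0 + 2 * r_px), radius_um=4.5, goblet=False,
                     granules=[], pattern=5, category=1),
    ]
    stack, _ = _manual_field(nuclei, spec)
    masks = detect_nuclei(fuse_stack(stack))
    assert len(masks) == 2


def test_granule_free_nucleus_detects_nothing(tiny_spec):
    nuclei = [NucleusTruth(center_px=(96.0, 96.0), radius_um=4.5, goblet=False,
                           granules=[], pattern=5, category=1)]
    stack, truth = _manual_field(nuclei, tiny_spec)
    fused = fuse_stack(stack)
    mask = truth.nuclei[0].mask(fused.image.shape[:2], tiny_spec.um_per_pixel)
    assert detect_granules(fused, mask) == []


def test_known_granules_recovered_with_diameters(tiny_spec):
    """Granules of 1.4 µm separated by > 2 µm: count exact, diameters
    within ±0.2 µm of truth."""
    spec = tiny_spec
    upp = spec.um_per_pixel
    centers_um = [(-2.5, -2.5), (-2.5, 2.5), (2.5, -2.5), (2.5, 2.5)]
    cy, cx = 96.0, 96.0
    granules = [
        GranuleTruth(center_px=(cy + dy / upp, cx + dx / upp), diameter_um=1.4, plane=i % 3)
        for i, (dy, dx) in enumerate(centers_um)
    ]
    nuclei = [NucleusTruth(center_px=(cy, cx), radius_um=5.0, goblet=False,
                           granules=granules, pattern=1, category=1)]
    stack, truth = _manual_field(nuclei, spec)
    fused = fuse_stack(stack)
    mask = truth.nuclei[0].mask(fused.image.shape[:2], upp)
    found = detect_granules(fused, mask)
    assert len(found) == 4
    for g in found:
        assert abs(g.equivalent_diameter_um - 1.4) <= 0.2


def test_faint_cytoplasmic_tint_produces_no_granules():
    """A uniform faint chromogen tint over a nucleus must stay below the
    granule redness threshold."""
    img = np.empty((64, 64, 3), dtype=float)
    img[:] = BACKGROUND_RGB
    rr, cc = np.mgrid[:64, :64]
    disk = (rr - 32) ** 2 + (cc - 32) ** 2 <= 18**2
    tinted = NUCLEUS_RGB + np.array([18.0, 5.0, 0.0])  # faint red-brown wash
    img[disk] = tinted
    fused = FusedImage(image=img.astype(np.uint8), um_per_pixel=0.25)
    assert detect_granules(fused, disk) == []
    # ... while the nucleus itself is still detected
    assert len(detect_nuclei(fused)) == 1


def test_category_counts_partition_counted_nuclei(tiny_spec):
    stack, _ = generate_specimen_stack(tiny_spec, 2)
    records, summary = score_fused_image(fuse_stack(stack))
    counted = [r for r in records if not r.goblet]
    assert all(r.pattern in (1, 2, 3, 4, 5) for r in counted)
    by_cat = {c: sum(1 for r in counted if r.category == c) for c in (1, 2, 3, 4)}
    assert sum(by_cat.values()) == summary.n_counted
    assert by_cat[2] + by_cat[3] + by_cat[4] == summary.n_positive
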