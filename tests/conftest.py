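import numpy as np
import pytest

from hifquant.synthetic import CohortSpec, GroupSpec


def make_tiny_spec() -> CohortSpec:
    """A small, fast cohort: 3 groups x few specimens, small fields."""
    return CohortSpec(
        groups=(
            GroupSpec("primary", 4, 15.0, 20.0),
            GroupSpec("recurrent", 2, 20.0, 30.0),
            GroupSpec("control", 3, 50.0, 30.0),
        ),
        nuclei_per_field=(6, 9),
        field_shape=(192, 192),
        seed=12345,
    )


@pytest.fixture
def tiny_spec() -> CohortSpec:
    return make_tiny_spec()


def iou_match(truth_mask: np.ndarray, masks: list[np.ndarray]):
    """Best-IoU detected mask for a truth mask; returns (mask, iou)."""
    best, best_iou = None, 0.0
    for m in masks:
        inter = np.logical_and(truth_mask, m).sum()
        if inter == 0:
            continue
        iou = inter / np.logical_or(truth_mask, m).sum()
        if iou > best_iou:
            best, best_iou = m, iou
    return best, best_iou
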