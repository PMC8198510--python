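"""Segmentation: band thresholds, bilateral denoising, component labeling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prophase3d.containers import ImageStack
from prophase3d.segmentation import (
    BAND_PRESETS,
    SegmentationBand,
    default_min_voxels,
    denoise_inplane,
    label_components,
    segment_stack,
    threshold_band,
    watershed_split,
)

SPACING = (44.0, 44.0, 100.0)


def test_band_presets_match_published_thresholds():
    assert (BAND_PRESETS["narrow"].min_intensity, BAND_PRESETS["narrow"].max_intensity) == (38445, 41264)
    assert (BAND_PRESETS["medium"].min_intensity, BAND_PRESETS["medium"].max_intensity) == (37596, 43832)
    assert (BAND_PRESETS["wide"].min_intensity, BAND_PRESETS["wide"].max_intensity) == (37498, 41346)


def test_band_validation():
    with pytest.raises(ValueError):
        SegmentationBand("bad", 100, 50)


@pytest.mark.parametrize(
    "value,band,expected",
    [(40000, "narrow", True), (37500, "narrow", False),
     (38445, "narrow", True), (41264, "narrow", True),  # inclusive bounds
     (43832, "medium", True), (43833, "medium", False)],
)
def test_threshold_band_inclusive(value, band, expected):
    stack = ImageStack(np.full((1, 2, 2), value, np.uint16), SPACING)
    assert threshold_band(stack, band).all() == expected


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 123456))
def test_narrow_mask_subset_of_medium(seed):
    """The narrow interval nests in the medium interval on any stack."""
    rng = np.random.default_rng(seed)
    data = rng.integers(30000, 50000, size=(3, 8, 8), dtype=np.uint16)
    narrow = threshold_band(data, "narrow")
    medium = threshold_band(data, "medium")
    assert not (narrow & ~medium).any()


def test_denoise_identity_at_zero_radius():
    rng = np.random.default_rng(0)
    stack = ImageStack(rng.integers(0, 65535, (2, 16, 16), dtype=np.uint16), SPACING)
    out = denoise_inplane(stack, spatial_radius=0)
    np.testing.assert_array_equal(out.data, stack.data)


def test_denoise_constant_stack_unchanged():
    stack = ImageStack(np.full((2, 16, 16), 40000, np.uint16), SPACING)
    out = denoise_inplane(stack, spatial_radius=2)
    np.testing.assert_array_equal(out.data, stack.data)


def test_denoise_reduces_interior_noise():
    """Noise std within a flat bright region strictly decreases per slice."""
    rng = np.random.default_rng(1)
    data = np.full((3, 64, 64), 40000.0)
    data += rng.normal(0, 150, data.shape)
    stack = ImageStack(np.clip(data, 0, 65535).astype(np.uint16), SPACING)
    out = denoise_inplane(stack, spatial_radius=2, range_sd=300.0)
    for k in range(3):
        before = stack.data[k, 8:-8, 8:-8].astype(float).std()
        after = out.data[k, 8:-8, 8:-8].astype(float).std()
        assert after < before


def _two_cubes(gap_voxels: int) -> np.ndarray:
    m = np.zeros((12, 12, 20), bool)
    m[3:8, 3:8, 2:7] = True
    m[3:8, 3:8, 7 + gap_voxels : 12 + gap_voxels] = True
    return m


def test_label_components_separated_cubes():
    labels = label_components(_two_cubes(gap_voxels=2), SPACING, min_voxels=1)
    assert len(labels.object_ids()) == 2


def test_label_components_size_filter():
    m = np.zeros((6, 6, 6), bool)
    m[2:4, 2:4, 2:4] = True  # 8 voxels
    labels = label_components(m, SPACING, min_voxels=100)
    assert len(labels.object_ids()) == 0


def test_labels_ordered_by_descending_size():
    m = np.zeros((5, 30, 8), bool)
    m[1:4, 1:11, 2:6] = True   # big
    m[1:3, 20:24, 2:5] = True  # small
    labels = label_components(m, SPACING, min_voxels=1)
    sizes = [(labels.data == i).sum() for i in labels.object_ids()]
    assert sizes == sorted(sizes, reverse=True)


@pytest.mark.parametrize("connectivity,n_expected", [(6, 2), (26, 1)])
def test_connectivity_semantics(connectivity, n_expected):
    """Two voxels touching only at a corner merge under 26 but not 6."""
    m = np.zeros((4, 4, 4), bool)
    m[1, 1, 1] = True
    m[2, 2, 2] = True
    labels = label_components(m, SPACING, connectivity=connectivity, min_voxels=1)
    assert len(labels.object_ids()) == n_expected


def _flood_fill_components(mask: np.ndarray) -> int:
    """Brute-force 26-connectivity component count (independent oracle)."""
    from collections import deque

    mask = mask.copy()
    offs = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    n = 0
    shape = mask.shape
    for start in zip(*np.nonzero(mask)):
        if not mask[start]:
            continue
        n += 1
        q = deque([start])
        mask[start] = False
        while q:
            z, y, x = q.popleft()
            for dz, dy, dx in offs:
                p = (z + dz, y + dy, x + dx)
                if (
                    0 <= p[0] < shape[0]
                    and 0 <= p[1] < shape[1]
                    and 0 <= p[2] < shape[2]
                    and mask[p]
                ):
                    mask[p] = False
                    q.append(p)
    return n


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 10**6))
def test_labeling_matches_flood_fill_oracle(seed):
    rng = np.random.default_rng(seed)
    mask = rng.random((10, 10, 10)) < 0.25
    labels = label_components(mask, SPACING, min_voxels=1)
    assert len(labels.object_ids()) == _flood_fill_components(mask)


def test_band_monotonicity_in_interval():
    """Enlarging the band interval never shrinks any component."""
    rng = np.random.default_rng(7)
    data = rng.integers(37000, 44500, (6, 20, 20), dtype=np.uint16)
    small = SegmentationBand("custom", 38000, 41000)
    big = SegmentationBand("custom", 37500, 43000)
    assert threshold_band(data, small).sum() <= threshold_band(data, big).sum()
    assert not (threshold_band(data, small) & ~threshold_band(data, big)).any()


def test_default_min_voxels_scales_with_voxel_volume():
    coarse = default_min_voxels((44, 44, 100))
    fine = default_min_voxels((11, 11, 25))
    assert fine == pytest.approx(coarse * 64, rel=0.05)


def test_segment_stack_warns_on_unexpected_count():
    stack = ImageStack(np.full((4, 10, 10), 40000, np.uint16), SPACING)
    with pytest.warns(UserWarning, match="expected 46"):
        segment_stack(stack, band="medium", min_voxels=1, expected_count=46)


def test_watershed_split_two_touching_blobs():
    """Two overlapping spheres merged into one object are split in two."""
    z, y, x = np.mgrid[0:20, 0:30, 0:20]
    blob1 = (z - 10) ** 2 + (y - 9) ** 2 + (x - 10) ** 2 <= 36
    blob2 = (z - 10) ** 2 + (y - 21) ** 2 + (x - 10) ** 2 <= 36
    merged = label_components(blob1 | blob2, (50.0, 50.0, 50.0), min_voxels=1)
    assert len(merged.object_ids()) == 1
    split = watershed_split(merged, min_distance_nm=300.0)
    assert len(split.object_ids()) == 2
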