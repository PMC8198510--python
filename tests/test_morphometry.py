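"""Morphometry on analytically constructed solids."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prophase3d.containers import LabelVolume
from prophase3d.morphometry import (
    dna_from_volume,
    genome_percentages,
    locate_centromere,
    measure_all,
    measure_chromosome,
    skeleton_longest_path,
)

SPACING = (44.0, 44.0, 100.0)  # (x, y, z) nm


def _cylinder(length_nm, radius_nm, spacing=SPACING, axis="x", radius_fn=None):
    """Solid cylinder (optionally with a varying radius profile) along an axis."""
    sx, sy, sz = spacing
    pad = 3
    nx = int(np.ceil(length_nm / sx)) + 2 * pad + int(2 * radius_nm / sx)
    ny = int(np.ceil(2 * radius_nm / sy)) + 2 * pad
    nz = int(np.ceil(2 * radius_nm / sz)) + 2 * pad
    z, y, x = np.mgrid[0:nz, 0:ny, 0:nx]
    px, py, pz = (x + 0.5) * sx, (y + 0.5) * sy, (z + 0.5) * sz
    x0 = (nx * sx - length_nm) / 2
    cy, cz = ny * sy / 2, nz * sz / 2
    along = px - x0
    r2 = (py - cy) ** 2 + (pz - cz) ** 2
    if radius_fn is None:
        rad = np.full_like(along, radius_nm)
    else:
        rad = radius_fn(along)
    mask = (along >= 0) & (along <= length_nm) & (r2 <= rad**2)
    if axis == "z":
        mask = np.transpose(mask, (2, 1, 0))
    return mask


class TestDnaConversion:
    def test_formula(self):
        assert dna_from_volume(5.80e6) == pytest.approx(1.0)
        assert dna_from_volume(0.0) == 0.0
        assert dna_from_volume(1.44362e9) == pytest.approx(248.9, rel=1e-4)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            dna_from_volume(-1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0, 1e12, allow_nan=False))
    def test_round_trip(self, v):
        assert dna_from_volume(v) * 5.80e6 == pytest.approx(v, rel=1e-12, abs=1e-9)


class TestSkeletonLength:
    def test_straight_cylinder_length(self):
        """A 2000 nm solid cylinder measures its axial length closely."""
        mask = _cylinder(2000.0, 180.0)
        path = skeleton_longest_path(mask, SPACING)
        diag = np.linalg.norm(SPACING)
        assert path.length_nm == pytest.approx(2000.0, abs=diag)

    def test_single_voxel_object(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        assert skeleton_longest_path(mask, SPACING).length_nm == 0.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            skeleton_longest_path(np.zeros((2, 2, 2), bool), SPACING)

    def test_axis_orientation_equivariance(self):
        """The same cylinder along x or z measures the same length."""
        lx = skeleton_longest_path(_cylinder(2000.0, 180.0, axis="x"), SPACING).length_nm
        # swap spacing accordingly: cylinder along z with (sz<->sx) swapped grid
        lz = skeleton_longest_path(
            _cylinder(2000.0, 180.0, axis="z"), (100.0, 44.0, 44.0)
        ).length_nm
        assert lx == pytest.approx(lz, rel=0.05)


class TestCentromere:
    @staticmethod
    def _waisted(ci_frac: float, length=3000.0, radius=200.0):
        """Cylinder with a Gaussian waist at ci_frac of its length."""
        s_c = ci_frac * length

        def radius_fn(s):
            return radius * (1 - 0.45 * np.exp(-((s - s_c) ** 2) / (2 * 150.0**2)))

        return _cylinder(length, radius, radius_fn=radius_fn)

    def test_symmetric_dumbbell_splits_at_midpoint(self):
        mask = self._waisted(0.5)
        path = skeleton_longest_path(mask, SPACING)
        cent = locate_centromere(mask, path, SPACING)
        assert cent.reliable
        assert cent.ci_len_percent == pytest.approx(50.0, abs=5.0)

    def test_offset_waist_recovers_ci(self):
        mask = self._waisted(0.25)
        path = skeleton_longest_path(mask, SPACING)
        cent = locate_centromere(mask, path, SPACING)
        assert cent.reliable
        assert cent.ci_len_percent == pytest.approx(25.0, abs=5.0)

    def test_uniform_cylinder_flagged_unreliable(self):
        mask = _cylinder(3000.0, 200.0)
        path = skeleton_longest_path(mask, SPACING)
        cent = locate_centromere(mask, path, SPACING)
        assert not cent.reliable

    def test_flat_profile_falls_back_to_prior(self):
        mask = _cylinder(3000.0, 200.0)
        path = skeleton_longest_path(mask, SPACING)
        cent = locate_centromere(mask, path, SPACING, expected_ci=30.0)
        assert not cent.reliable
        assert cent.ci_len_percent == pytest.approx(30.0, abs=6.0)


class TestMeasureChromosome:
    def test_cube_volume_exact(self):
        data = np.zeros((14, 14, 14), np.int32)
        data[2:12, 2:12, 2:12] = 1
        labels = LabelVolume(data, (11.0, 11.0, 25.0))
        m = measure_chromosome(labels, 1)
        assert m.volume_nm3 == pytest.approx(1000 * 11 * 11 * 25)
        assert m.dna_mbp == pytest.approx(m.volume_nm3 / 5.80e6)

    def test_cylinder_mean_diameter(self):
        mask = _cylinder(2600.0, 300.0)
        labels = LabelVolume(mask.astype(np.int32), SPACING)
        m = measure_chromosome(labels, 1)
        assert m.mean_diameter_nm == pytest.approx(600.0, abs=2 * max(SPACING))

    def test_missing_object_rejected(self):
        labels = LabelVolume(np.ones((3, 3, 3), np.int32), SPACING)
        with pytest.raises(KeyError):
            measure_chromosome(labels, 7)

    def test_invariants_on_waisted_rod(self):
        mask = TestCentromere._waisted(0.3)
        labels = LabelVolume(mask.astype(np.int32), SPACING)
        m = measure_chromosome(labels, 1)
        assert m.p_len_nm <= m.q_len_nm
        assert m.total_len_nm == pytest.approx(m.p_len_nm + m.q_len_nm)
        assert 0 < m.ci_len_percent <= 50
        assert m.p_vol_nm3 + m.q_vol_nm3 == pytest.approx(m.volume_nm3)

    def test_scale_equivariance(self):
        """Scaling the voxel spacing scales lengths by s and volumes by s^3."""
        mask = TestCentromere._waisted(0.35)
        m1 = measure_chromosome(LabelVolume(mask.astype(np.int32), SPACING), 1)
        s = 2.0
        sc = tuple(v * s for v in SPACING)
        m2 = measure_chromosome(LabelVolume(mask.astype(np.int32), sc), 1)
        assert m2.volume_nm3 == pytest.approx(m1.volume_nm3 * s**3)
        assert m2.total_len_nm == pytest.approx(m1.total_len_nm * s, rel=1e-6)


class TestGenomePercentages:
    def test_two_equal_objects(self):
        data = np.zeros((6, 6, 14), np.int32)
        data[1:5, 1:5, 1:5] = 1
        data[1:5, 1:5, 8:12] = 2
        labels = LabelVolume(data, SPACING)
        df = measure_all(labels)
        assert df["vol_percent_of_genome"].tolist() == pytest.approx([50.0, 50.0])
        assert df["vol_percent_of_genome"].sum() == pytest.approx(100.0, abs=1e-6)
        assert df["len_percent_of_genome"].sum() == pytest.approx(100.0, abs=1e-6)

    def test_single_object_is_hundred_percent(self):
        data = np.zeros((6, 6, 6), np.int32)
        data[1:5, 1:5, 1:5] = 1
        df = measure_all(LabelVolume(data, SPACING))
        assert df["vol_percent_of_genome"].iloc[0] == pytest.approx(100.0)

    def test_empty_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            genome_percentages(pd.DataFrame())
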