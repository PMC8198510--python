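"""Synthetic nucleus generator: geometry, rendering, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from prophase3d.phantom import PhantomConfig, PlacementError, generate_phantom, make_chromosome_solid
from prophase3d.reference import NM3_PER_BP
from prophase3d.segmentation import threshold_band


class TestConfig:
    def test_band_level_invariants_enforced(self):
        with pytest.raises(ValueError, match="narrow"):
            PhantomConfig(background_level=39000)
        with pytest.raises(ValueError, match="axis_level"):
            PhantomConfig(axis_level=45000)

    def test_coarse_preset(self):
        cfg = PhantomConfig.coarse(seed=7)
        assert cfg.voxel_nm == (44.0, 44.0, 100.0)
        assert cfg.noise_sd == 0.0

    def test_nucleus_fits_grid_with_margin(self):
        cfg = PhantomConfig.coarse()
        nz, ny, nx = cfg.grid_shape
        sx, sy, sz = cfg.voxel_nm
        assert nx * sx >= cfg.nucleus_diameter_nm + 2 * cfg.margin_voxels * sx
        assert nz * sz >= cfg.nucleus_diameter_nm + 2 * cfg.margin_voxels * sz


class TestChromosomeSolid:
    def test_medium_envelope_volume_matches_dna_content(self, reference):
        """Chromosome 1 voxel volume ~ 248.9e6 bp x 5.80 nm^3 within 10%."""
        cfg = PhantomConfig.coarse(seed=0)
        sol = make_chromosome_solid(reference.entry("1"), cfg, 0)
        target = 248.9e6 * NM3_PER_BP
        assert sol.volume_nm3 == pytest.approx(target, rel=0.10)

    @pytest.mark.parametrize("chrom", ["1", "13", "21", "X"])
    def test_single_connected_component(self, reference, chrom):
        cfg = PhantomConfig.coarse(seed=1)
        sol = make_chromosome_solid(reference.entry(chrom), cfg, 1)
        bbox_shape = tuple(s.stop - s.start for s in sol.bbox)
        mask = np.zeros(bbox_shape, bool)
        mask[sol.d_norm <= 1.0] = True
        n = ndimage.label(mask, structure=np.ones((3, 3, 3)))[1]
        assert n == 1

    def test_ci_matches_canonical(self, reference):
        for chrom in ("1", "4", "13", "21"):
            cfg = PhantomConfig.coarse(seed=2)
            sol = make_chromosome_solid(reference.entry(chrom), cfg, 2)
            canonical = reference.canonical_ci(chrom)
            assert sol.ci_percent == pytest.approx(canonical, rel=0.05)

    def test_metacentric_symmetric_arms(self, reference):
        entry = reference.entry("1").copy()
        entry["canonical_ci"] = 50.0
        cfg = PhantomConfig.coarse(seed=3)
        sol = make_chromosome_solid(entry, cfg, 3)
        assert abs(sol.p_len_nm - sol.q_len_nm) <= max(cfg.voxel_nm)

    def test_straight_skeleton_when_unbent(self, reference):
        cfg = PhantomConfig.coarse(seed=4, bend_deg=0.0)
        sol = make_chromosome_solid(reference.entry("2"), cfg, 4)
        pts = sol.skeleton_nm
        chord = np.linalg.norm(pts[-1] - pts[0])
        arc = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert chord == pytest.approx(arc, rel=0.01)

    def test_oversized_chromosome_rejected(self, reference):
        cfg = PhantomConfig.coarse(seed=5, volume_scale=40.0)
        with pytest.raises((PlacementError, ValueError)):
            make_chromosome_solid(reference.entry("1"), cfg, 5)


class TestGeneratePhantom:
    def test_forty_six_distinct_objects(self, coarse_phantom):
        labels = coarse_phantom["truth_labels"]
        assert len(labels.object_ids()) == 46
        truth = coarse_phantom["truth"]
        assert len(truth) == 46
        counts = truth["chrom_id"].value_counts()
        assert counts["X"] == 1 and counts["Y"] == 1
        assert (counts.drop(["X", "Y"]) == 2).all()

    def test_empty_karyotype(self, reference):
        cfg = PhantomConfig.coarse(seed=0, chromosomes=())
        stack, labels, truth = generate_phantom(cfg, reference)
        assert labels.data.max() == 0
        assert len(truth) == 0
        assert (stack.data == cfg.background_level).all()

    def test_reproducibility(self, reference):
        cfg = PhantomConfig.coarse(seed=11, chromosomes=("1", "2", "19", "21"))
        a = generate_phantom(cfg, reference)
        b = generate_phantom(cfg, reference)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[1].data, b[1].data)
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_no_voxel_shared_and_mass_conserved(self, coarse_phantom):
        labels = coarse_phantom["truth_labels"]
        truth = coarse_phantom["truth"]
        voxel_vol = labels.voxel_volume_nm3
        assert (np.bincount(labels.data.ravel())[1:] > 0).all()
        total = truth["true_volume_nm3"].sum()
        cfg = coarse_phantom["config"]
        sphere = 4 / 3 * np.pi * (cfg.nucleus_diameter_nm / 2) ** 3
        assert total <= sphere
        # per-object truth volume equals labeled voxel count x voxel volume
        counts = np.bincount(labels.data.ravel())
        for _, row in truth.iterrows():
            assert counts[int(row.object_id)] * voxel_vol == pytest.approx(
                row.true_volume_nm3
            )

    def test_objects_inside_nuclear_sphere(self, coarse_phantom):
        labels = coarse_phantom["truth_labels"]
        cfg = coarse_phantom["config"]
        sx, sy, sz = cfg.voxel_nm
        vox = np.argwhere(labels.data > 0)
        pts = (vox[:, ::-1] + 0.5) * np.array([sx, sy, sz])
        d = np.linalg.norm(pts - cfg.center_nm, axis=1)
        assert d.max() <= cfg.nucleus_diameter_nm / 2 + 1e-6

    def test_band_nesting_on_noiseless_stack(self, coarse_phantom):
        stack = coarse_phantom["stack"]
        narrow = threshold_band(stack, "narrow")
        medium = threshold_band(stack, "medium")
        assert not (narrow & ~medium).any()
        assert narrow.sum() < medium.sum()

    def test_graded_envelopes_per_object(self, coarse_phantom):
        """narrow < medium <= wide mask volume for every chromosome."""
        stack = coarse_phantom["stack"].data
        labels = coarse_phantom["truth_labels"]
        narrow = threshold_band(stack, "narrow")
        medium = threshold_band(stack, "medium")
        # wide adds the halo, which lies outside the labeled solid; compare
        # within a one-voxel-dilated neighborhood of each object
        wide = threshold_band(stack, "wide")
        for oid in labels.object_ids():
            obj = labels.data == oid
            grown = ndimage.binary_dilation(obj, np.ones((3, 3, 3)), iterations=2)
            n = (narrow & obj).sum()
            m = (medium & obj).sum()
            w = (wide & grown).sum()
            assert n < m <= w

    def test_true_radius_consistent_with_centroid(self, coarse_phantom):
        truth = coarse_phantom["truth"]
        cfg = coarse_phantom["config"]
        c = cfg.center_nm
        d = np.linalg.norm(
            truth[["centroid_x_nm", "centroid_y_nm", "centroid_z_nm"]].to_numpy() - c,
            axis=1,
        )
        np.testing.assert_allclose(d, truth["true_radius_nm"].to_numpy(), atol=1e-6)

    def test_homolog_volumes_near_identical_not_equal(self, coarse_phantom):
        truth = coarse_phantom["truth"]
        for chrom, sub in truth.groupby("chrom_id"):
            if len(sub) == 2:
                va, vb = sub["true_volume_nm3"].to_numpy()
                assert va != vb
                assert abs(va - vb) / max(va, vb) < 0.08


def test_radial_bias_accepted_by_config():
    cfg = PhantomConfig.coarse(radial_bias=6.0)
    assert cfg.radial_bias == 6.0
    with pytest.raises(ValueError):
        PhantomConfig.coarse(radial_bias=-1.0)
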