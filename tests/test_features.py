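"""Atlas reslicing, region averaging, design-matrix assembly."""

import numpy as np
import pytest

import dtdecode as dd
from dtdecode.features import LabelVolume, RegionFeatureRow


@pytest.fixture()
def toy():
    label_img, gm_img, wm_img = dd.generate_toy_volumes(
        (9, 4, 4), n_regions=2, seed=0, gm_values=[0.3, 0.7],
        wm_values=[0.2, 0.4])
    return (LabelVolume.from_image(label_img), gm_img, wm_img)


class TestRegionMeans:
    def test_constant_per_region_fixture(self, toy):
        labels, gm_img, wm_img = toy
        np.testing.assert_allclose(dd.region_means(gm_img, labels), [0.3, 0.7])
        np.testing.assert_allclose(dd.region_means(wm_img, labels), [0.2, 0.4])

    def test_constant_volume_gives_constant_means(self, toy):
        labels = toy[0]
        vol = np.full(labels.voxels.shape, 0.42)
        np.testing.assert_allclose(dd.region_means(vol, labels), [0.42, 0.42])

    def test_matches_voxel_loop_oracle(self, rng):
        label_img, gm_img, _ = dd.generate_toy_volumes((9, 4, 4), 2, seed=3)
        labels = LabelVolume.from_image(label_img)
        data = np.asarray(gm_img.dataobj)
        means = dd.region_means(gm_img, labels)
        for i, lab in enumerate(labels.labels):
            voxels = [data[x, y, z]
                      for x in range(9) for y in range(4) for z in range(4)
                      if labels.voxels[x, y, z] == lab]
            assert means[i] == pytest.approx(np.mean(voxels), rel=1e-12)

    def test_empty_region_yields_nan_with_warning(self, toy):
        labels = toy[0]
        vol = np.ones(labels.voxels.shape)
        with pytest.warns(UserWarning, match="empty"):
            means = dd.region_means(vol, labels, region_labels=[1, 2, 3])
        assert np.isnan(means[2]) and not np.isnan(means[:2]).any()

    def test_background_only_volume_signals_empty_region(self):
        labels = LabelVolume(voxels=np.zeros((3, 3, 3), dtype=int),
                             affine=np.eye(4))
        with pytest.warns(UserWarning):
            means = dd.region_means(np.ones((3, 3, 3)), labels,
                                    region_labels=[1])
        assert np.isnan(means).all()

    def test_grid_mismatch_rejected(self, toy):
        with pytest.raises(ValueError):
            dd.region_means(np.ones((2, 2, 2)), toy[0])

    def test_permutation_equivariant_in_label_order(self, toy):
        labels, gm_img, _ = toy
        fwd = dd.region_means(gm_img, labels, region_labels=[1, 2])
        rev = dd.region_means(gm_img, labels, region_labels=[2, 1])
        np.testing.assert_array_equal(fwd, rev[::-1])


class TestReslice:
    def test_identity_reslice_is_voxel_identical(self, toy):
        labels = toy[0]
        out = dd.reslice_labels(labels, (labels.voxels.shape, labels.affine))
        np.testing.assert_array_equal(out.voxels, labels.voxels)

    def test_one_voxel_translation_shifts_labels(self, toy):
        labels = toy[0]
        ref_affine = labels.affine.copy()
        ref_affine[0, 3] += 1.0  # reference shifted +1 mm along x
        out = dd.reslice_labels(labels, (labels.voxels.shape, ref_affine))
        # brute-force coordinate mapping: ref voxel i sits at label voxel i+1
        expected = np.zeros_like(labels.voxels)
        expected[:-1] = labels.voxels[1:]
        np.testing.assert_array_equal(out.voxels, expected)

    def test_reslice_then_means_equals_direct_means(self, toy):
        labels, gm_img, _ = toy
        resliced = dd.reslice_labels(labels, gm_img)
        np.testing.assert_array_equal(
            dd.region_means(gm_img, resliced),
            dd.region_means(gm_img, labels))

    def test_label_set_never_grows(self, toy):
        labels = toy[0]
        ref_affine = labels.affine.copy()
        ref_affine[:3, :3] *= 2.0  # coarser grid
        out = dd.reslice_labels(labels, ((5, 2, 2), ref_affine))
        assert set(out.labels) <= set(labels.labels)

    def test_singular_affine_rejected(self, toy):
        labels = toy[0]
        bad = np.zeros((4, 4))
        with pytest.raises(ValueError, match="singular"):
            dd.reslice_labels(labels, ((3, 3, 3), bad))
        with pytest.raises(ValueError, match="singular"):
            dd.reslice_labels(LabelVolume(labels.voxels, bad),
                              ((3, 3, 3), np.eye(4)))


class TestToyVolumes:
    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            dd.generate_toy_volumes((2, 4, 4), n_regions=5)

    def test_deterministic(self):
        a = dd.generate_toy_volumes((9, 4, 4), 2, seed=11)
        b = dd.generate_toy_volumes((9, 4, 4), 2, seed=11)
        np.testing.assert_array_equal(np.asarray(a[1].dataobj),
                                      np.asarray(b[1].dataobj))

    def test_nifti_round_trip(self, tmp_path):
        import nibabel as nib
        label_img, gm_img, _ = dd.generate_toy_volumes((9, 4, 4), 2, seed=0,
                                                       gm_values=[0.3, 0.7])
        nib.save(label_img, tmp_path / "atlas.nii.gz")
        nib.save(gm_img, tmp_path / "gm.nii.gz")
        labels = LabelVolume.from_image(nib.load(tmp_path / "atlas.nii.gz"))
        gm = nib.load(tmp_path / "gm.nii.gz")
        np.testing.assert_allclose(dd.region_means(gm, labels), [0.3, 0.7],
                                   rtol=1e-6)


class TestBuildDesignMatrix:
    @staticmethod
    def _rows(n, R, rng):
        return [RegionFeatureRow(f"s{i}", rng.random(R), rng.random(R))
                for i in range(n)]

    def test_column_count_formula(self, rng):
        rows = self._rows(5, 116, rng)
        site = np.arange(5) % 17
        design, roles = dd.build_design_matrix(
            rows, site, ["f", "m", "f", "m", "f"],
            site_levels=np.arange(17))
        assert design.shape == (5, 2 * 116 + 17 + 1) == (5, 250)
        assert roles.shape == (250,)

    @pytest.mark.parametrize("R,S", [(1, 1), (3, 2), (10, 5)])
    def test_column_count_holds_generally(self, R, S, rng):
        rows = self._rows(4, R, rng)
        design, _ = dd.build_design_matrix(
            rows, np.arange(4) % S, [1, -1, 1, -1], site_levels=np.arange(S))
        assert design.shape[1] == 2 * R + S + 1

    def test_minimal_single_subject_row(self, rng):
        rows = [RegionFeatureRow("s0", [0.5], [0.3])]
        design, roles = dd.build_design_matrix(rows, ["a"], ["f"])
        np.testing.assert_allclose(design, [[0.5, 0.3, 1.0, 1.0]])
        assert list(roles) == ["gm_region", "wm_region", "site", "gender"]

    def test_gender_coding_lexicographic(self, rng):
        rows = self._rows(3, 1, rng)
        design, roles = dd.build_design_matrix(rows, [0, 0, 0],
                                               ["m", "f", "m"])
        gender = design[:, roles == "gender"].ravel()
        np.testing.assert_array_equal(gender, [-1.0, 1.0, -1.0])
        assert set(gender) <= {1.0, -1.0}

    def test_unseen_site_level_rejected(self, rng):
        rows = self._rows(2, 1, rng)
        with pytest.raises(ValueError, match="site"):
            dd.build_design_matrix(rows, ["siteX", "siteY"], [1, -1],
                                   site_levels=["siteX"])

    def test_extract_features_end_to_end(self, toy):
        labels, gm_img, wm_img = toy
        data = dd.extract_features(
            [gm_img, gm_img], [wm_img, wm_img], labels,
            subject_ids=["s1", "s2"], site=["a", "b"], gender=["f", "m"],
            ages=[30.0, 60.0])
        assert data.p == 2 * 2 + 2 + 1
        np.testing.assert_allclose(data.block("gm_region"),
                                   [[0.3, 0.7], [0.3, 0.7]])
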