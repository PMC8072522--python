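"""Lesion masking, ROI extraction and hemispheric orientation."""

import numpy as np
import pytest

from strokeconn.atlas import (
    RoiAtlas,
    RoiLabel,
    apply_lesion_mask,
    extract_roi_series,
    load_manifest,
    manifest_to_labels,
    labels_to_manifest,
    orient_matrix,
    orientation_permutation,
    pair_compartment,
    save_manifest,
)


def four_roi_atlas():
    """2 homologous pairs on a 4x2x1 grid: ids 1/2 = pair A (L/R), 3/4 = pair B."""
    vol = np.zeros((4, 2, 1), dtype=int)
    vol[0, 0, 0] = 1
    vol[3, 0, 0] = 2
    vol[0, 1, 0] = 3
    vol[3, 1, 0] = 4
    labels = [
        RoiLabel(1, "a_left", "left", 2),
        RoiLabel(2, "a_right", "right", 1),
        RoiLabel(3, "b_left", "left", 4),
        RoiLabel(4, "b_right", "right", 3),
    ]
    return RoiAtlas(label_volume=vol, labels=labels)


class TestRoiAtlasValidation:
    def test_unknown_voxel_label_rejected(self):
        vol = np.array([[[9]]])
        with pytest.raises(ValueError, match="absent"):
            RoiAtlas(vol, [RoiLabel(1, "x", "midline", None)])

    def test_homologue_must_be_involution(self):
        labels = [
            RoiLabel(1, "a", "left", 2),
            RoiLabel(2, "b", "right", None),
        ]
        with pytest.raises(ValueError):
            RoiAtlas(np.zeros((1, 1, 1), int), labels)

    def test_midline_has_no_homologue(self):
        labels = [RoiLabel(1, "m", "midline", 1)]
        with pytest.raises(ValueError, match="midline"):
            RoiAtlas(np.zeros((1, 1, 1), int), labels)

    def test_manifest_roundtrip(self, tmp_path):
        atlas = four_roi_atlas()
        path = tmp_path / "labels.json"
        save_manifest(atlas.labels, path)
        assert load_manifest(path) == atlas.labels
        assert manifest_to_labels(labels_to_manifest(atlas.labels)) == atlas.labels


class TestLesionMasking:
    def test_empty_lesion_keeps_everything(self):
        atlas = four_roi_atlas()
        sub = apply_lesion_mask(atlas, np.zeros(atlas.label_volume.shape, bool))
        assert sub.surviving_counts == sub.original_counts
        assert all(sub.availability.values())

    def test_partial_lesion_reduces_count(self):
        vol = np.zeros((5, 2, 1), int)
        vol[:, 0, 0] = 1  # 5-voxel ROI
        atlas = RoiAtlas(vol, [RoiLabel(1, "m", "midline", None)])
        lesion = np.zeros(vol.shape, bool)
        lesion[:2, 0, 0] = True  # 40% of the ROI
        sub = apply_lesion_mask(atlas, lesion)
        assert sub.surviving_counts[1] == 3
        assert sub.availability[1]

    def test_full_lesion_marks_unavailable(self):
        atlas = four_roi_atlas()
        lesion = atlas.label_volume == 1
        sub = apply_lesion_mask(atlas, lesion, lesion_side="left")
        assert not sub.availability[1]
        assert all(sub.availability[i] for i in (2, 3, 4))

    def test_masking_disabled_reproduces_base_atlas(self):
        atlas = four_roi_atlas()
        lesion = atlas.label_volume == 1
        sub = apply_lesion_mask(atlas, lesion, enabled=False)
        assert sub.surviving_counts == sub.original_counts

    def test_grid_mismatch_raises(self):
        atlas = four_roi_atlas()
        with pytest.raises(ValueError, match="aligned"):
            apply_lesion_mask(atlas, np.zeros((2, 2, 2), bool))


class TestExtraction:
    def test_identical_voxels_reproduce_series(self):
        vol = np.zeros((4, 1, 1), int)
        vol[:2, 0, 0] = 1
        atlas = RoiAtlas(vol, [RoiLabel(1, "m", "midline", None)])
        sub = apply_lesion_mask(atlas, None)
        bold = np.zeros((4, 1, 1, 5))
        series = np.array([1.0, 2, 3, 4, 5])
        bold[0, 0, 0] = series
        bold[1, 0, 0] = series
        out, avail = extract_roi_series(bold, sub)
        np.testing.assert_allclose(out[:, 0], series)
        assert avail[0]

    def test_opposite_series_cancel(self):
        vol = np.zeros((2, 1, 1), int)
        vol[:, 0, 0] = 1
        atlas = RoiAtlas(vol, [RoiLabel(1, "m", "midline", None)])
        sub = apply_lesion_mask(atlas, None)
        bold = np.zeros((2, 1, 1, 4))
        bold[0, 0, 0] = [1, -2, 3, -4]
        bold[1, 0, 0] = [-1, 2, -3, 4]
        out, _ = extract_roi_series(bold, sub)
        np.testing.assert_allclose(out[:, 0], 0)

    def test_masking_homogeneous_roi_leaves_mean_unchanged(self):
        vol = np.zeros((4, 1, 1), int)
        vol[:, 0, 0] = 1
        atlas = RoiAtlas(vol, [RoiLabel(1, "m", "midline", None)])
        rng = np.random.default_rng(0)
        series = rng.standard_normal(6)
        bold = np.broadcast_to(series, (4, 1, 1, 6)).copy()
        lesion = np.zeros(vol.shape, bool)
        lesion[:2, 0, 0] = True
        full = extract_roi_series(bold, apply_lesion_mask(atlas, None))[0]
        half = extract_roi_series(bold, apply_lesion_mask(atlas, lesion))[0]
        np.testing.assert_allclose(full, half)

    def test_lesion_sentinel_never_contributes(self):
        atlas = four_roi_atlas()
        rng = np.random.default_rng(1)
        bold = rng.standard_normal(atlas.label_volume.shape + (8,))
        lesion = atlas.label_volume == 3
        poisoned = bold.copy()
        poisoned[lesion] = 1e9  # sentinel
        clean_sub = apply_lesion_mask(atlas, lesion, lesion_side="left")
        a, avail = extract_roi_series(bold, clean_sub)
        b, _ = extract_roi_series(poisoned, clean_sub)
        np.testing.assert_array_equal(
            np.nan_to_num(a, nan=-1), np.nan_to_num(b, nan=-1)
        )
        assert not avail[2]  # the fully lesioned ROI is missing, not zero
        assert np.all(np.isnan(a[:, 2]))


class TestOrientation:
    def test_right_lesion_is_identity(self):
        atlas = four_roi_atlas()
        perm = orientation_permutation(atlas.labels, "right")
        np.testing.assert_array_equal(perm, np.arange(4))

    def test_double_application_is_identity(self):
        atlas = four_roi_atlas()
        perm = orientation_permutation(atlas.labels, "left")
        rng = np.random.default_rng(2)
        m = rng.standard_normal((4, 4))
        np.testing.assert_allclose(orient_matrix(orient_matrix(m, perm), perm), m)

    def test_left_lesion_hand_computed_permutation(self):
        atlas = four_roi_atlas()
        perm = orientation_permutation(atlas.labels, "left")
        m = np.arange(16, dtype=float).reshape(4, 4)
        out = orient_matrix(m, perm)
        # homologue swap: positions (0,1) exchange, (2,3) exchange
        expected = m[np.ix_([1, 0, 3, 2], [1, 0, 3, 2])]
        np.testing.assert_array_equal(out, expected)

    def test_no_lesion_side_rejected(self):
        atlas = four_roi_atlas()
        with pytest.raises(ValueError, match="lesion side"):
            orientation_permutation(atlas.labels, "none")

    def test_orientation_commutes_with_correlation(self):
        atlas = four_roi_atlas()
        perm = orientation_permutation(atlas.labels, "left")
        rng = np.random.default_rng(3)
        series = rng.standard_normal((40, 4))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(4)
        corr_then_orient = orient_matrix(np.corrcoef(series, rowvar=False), perm)
        orient_then_corr = np.corrcoef(series[:, inv], rowvar=False)
        np.testing.assert_allclose(corr_then_orient, orient_then_corr, atol=1e-12)


class TestCompartments:
    def test_partition_of_lateralized_pairs(self):
        atlas = four_roi_atlas()
        assert pair_compartment(atlas.labels, 0, 1) == "inter"
        assert pair_compartment(atlas.labels, 1, 3) == "ipsi_intra"
        assert pair_compartment(atlas.labels, 0, 2) == "contra_intra"

    def test_midline_pairs_have_no_compartment(self):
        labels = [
            RoiLabel(1, "a", "left", 2),
            RoiLabel(2, "b", "right", 1),
            RoiLabel(3, "m", "midline", None),
        ]
        assert pair_compartment(labels, 0, 2) is None
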