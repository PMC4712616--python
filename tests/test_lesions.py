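"""Lesion growing, NAWM thresholds, four-class rule, ROI file dialect."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msquant.image import VolumeImage
from msquant.lesions import (NAWM_REF, UNCLASSIFIED, Roi, RoiSet, class_masks,
                             classification_thresholds, classify_lesions,
                             grow_lesion_roi, nawm_stats, read_roiset,
                             write_roiset)


def _volume(data):
    return VolumeImage(np.asarray(data, dtype=float), np.eye(4), space="flair")


def _sphere_image(shape=(20, 20, 20), center=(10, 10, 10), radius=2.6,
                  background=40.0, lesion=100.0):
    g = np.ogrid[:shape[0], :shape[1], :shape[2]]
    d2 = sum((gi - c) ** 2 for gi, c in zip(g, center))
    data = np.full(shape, background)
    data[d2 <= radius ** 2] = lesion
    return _volume(data), int((d2 <= radius ** 2).sum())


class TestGrowLesionRoi:
    def test_recovers_exact_sphere(self):
        img, n_truth = _sphere_image()
        roi = grow_lesion_roi(img, (10, 10, 10), local_factor=0.5)
        assert roi.n_voxels == n_truth == 81

    def test_strict_peak_with_factor_one_yields_seed_only(self):
        data = np.full((7, 7, 7), 10.0)
        data[3, 3, 3] = 50.0
        roi = grow_lesion_roi(_volume(data), (3, 3, 3), local_factor=1.0)
        assert roi.voxels == [(3, 3, 3)]

    def test_disjoint_sphere_not_included(self):
        img_a, _ = _sphere_image(center=(5, 5, 5))
        data = img_a.data.copy()
        g = np.ogrid[:20, :20, :20]
        d2 = sum((gi - c) ** 2 for gi, c in zip(g, (15, 15, 15)))
        data[d2 <= 2.6 ** 2] = 100.0
        roi = grow_lesion_roi(_volume(data), (5, 5, 5), local_factor=0.5)
        far = [v for v in roi.voxels if sum((a - b) ** 2 for a, b in zip(v, (15, 15, 15))) <= 7]
        assert not far

    def test_boundary_touch_sets_warning(self):
        data = np.full((8, 8, 8), 10.0)
        data[0:3, 4, 4] = 100.0
        roi = grow_lesion_roi(_volume(data), (1, 4, 4), local_factor=0.6)
        assert any("boundary" in w for w in roi.warnings)

    def test_seed_outside_grid_rejected(self):
        img, _ = _sphere_image()
        with pytest.raises(ValueError):
            grow_lesion_roi(img, (50, 0, 0))


class TestNawmStats:
    def test_constant_region(self):
        img = _volume(np.full((5, 5, 5), 100.0))
        roi = Roi(id=0, voxels=[(0, 0, 0), (1, 1, 1), (2, 2, 2)], class_code=NAWM_REF)
        assert nawm_stats(img, roi) == (100.0, 0.0)

    def test_two_point_sample_sd(self):
        data = np.zeros((3, 3, 3))
        data[0, 0, 0], data[1, 1, 1] = 90.0, 110.0
        roi = Roi(id=0, voxels=[(0, 0, 0), (1, 1, 1)], class_code=NAWM_REF)
        mean, sd = nawm_stats(_volume(data), roi)
        assert mean == 100.0
        assert sd == pytest.approx(14.142135623730951)

    def test_single_voxel_rejected(self):
        roi = Roi(id=0, voxels=[(0, 0, 0)], class_code=NAWM_REF)
        with pytest.raises(ValueError):
            nawm_stats(_volume(np.zeros((2, 2, 2))), roi)

    def test_non_reference_roi_rejected(self):
        roi = Roi(id=1, voxels=[(0, 0, 0), (1, 0, 0)])
        with pytest.raises(ValueError):
            nawm_stats(_volume(np.zeros((2, 2, 2))), roi)


class TestClassificationThresholds:
    @given(mean=st.floats(-1e4, 1e4), sd=st.floats(0, 1e3), mf=st.floats(0, 10))
    def test_matches_independent_arithmetic(self, mean, sd, mf):
        thr = classification_thresholds(mean, sd, mf)
        assert thr.thre_high == pytest.approx(mean + mf * sd, abs=1e-12, rel=1e-12)
        assert thr.thre_low == pytest.approx(mean - mf * sd, abs=1e-12, rel=1e-12)
        assert thr.thre_low <= thr.thre_high

    @pytest.mark.parametrize("mean,sd,mf,lo,hi", [
        (100, 5, 2, 90, 110),
        (100, 0, 3.7, 100, 100),
        (100, 5, 0, 100, 100),
    ])
    def test_window_arithmetic(self, mean, sd, mf, lo, hi):
        thr = classification_thresholds(mean, sd, mf)
        assert (thr.thre_low, thr.thre_high) == (lo, hi)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            classification_thresholds(100, -1, 2)


def _classification_setup(t1_lesion, gd_lesion, nawm_mean=100.0, spread=5.0):
    """NAWM with mean 100 / sd ~5 on both modalities plus one lesion."""
    shape = (12, 12, 6)
    rng = np.random.default_rng(1)
    nawm_vox = [(x, y, 1) for x in range(8) for y in range(8)]
    lesion_vox = [(x, y, 4) for x in range(3) for y in range(3)]
    t1 = np.full(shape, nawm_mean)
    gd = np.full(shape, nawm_mean)
    noise = rng.normal(0, spread, size=len(nawm_vox))
    for (v, n) in zip(nawm_vox, noise):
        t1[v] = gd[v] = nawm_mean + n
    for v in lesion_vox:
        t1[v], gd[v] = t1_lesion, gd_lesion
    rois = RoiSet([Roi(id=0, voxels=nawm_vox, class_code=NAWM_REF),
                   Roi(id=1, voxels=lesion_vox)])
    return rois, _volume(t1), _volume(gd)


class TestClassifyLesions:
    @pytest.mark.parametrize("t1_mean,gd_mean,expected", [
        (99, 160, "C1"),    # enhancing, isointense
        (60, 160, "C2"),    # enhancing, hypointense
        (99, 95, "C3"),     # non-enhancing, isointense
        (60, 95, "C4"),     # black hole
    ])
    def test_four_class_rule(self, t1_mean, gd_mean, expected):
        rois, t1, gd = _classification_setup(t1_mean, gd_mean)
        out = classify_lesions(rois, t1, gd, mf=2.0)
        assert out.by_id(1).class_code == expected

    def test_threshold_equality_counts_as_isointense(self):
        # degenerate NAWM (sd = 0): lesion exactly at the mean stays C3
        rois, t1, gd = _classification_setup(100, 100, spread=0.0)
        out = classify_lesions(rois, t1, gd, mf=2.0)
        assert out.by_id(1).class_code == "C3"

    def test_t1_hyperintense_mapped_to_isointense_with_warning(self):
        rois, t1, gd = _classification_setup(160, 95)
        out = classify_lesions(rois, t1, gd, mf=2.0)
        roi = out.by_id(1)
        assert roi.class_code == "C3"
        assert any("hyperintense" in w for w in roi.warnings)

    def test_acute_chronic_flag_in_label(self):
        rois, t1, gd = _classification_setup(60, 160)
        out = classify_lesions(rois, t1, gd, mf=2.0)
        assert "acute" in out.by_id(1).label_text

    @given(a=st.floats(0.1, 50), b=st.floats(-200, 200))
    def test_invariant_to_global_affine_rescaling(self, a, b):
        rois, t1, gd = _classification_setup(60, 160)
        base = [r.class_code for r in classify_lesions(rois, t1, gd, mf=2.0).lesions()]
        t1s = t1.like(a * t1.data + b)
        gds = gd.like(a * gd.data + b)
        scaled = [r.class_code for r in classify_lesions(rois, t1s, gds, mf=2.0).lesions()]
        assert base == scaled

    def test_phantom_truth_recovered(self, noiseless_bundle):
        b = noiseless_bundle
        rois = [Roi(id=0, voxels=b.nawm_ref_voxels, class_code=NAWM_REF)]
        for lid, seed in sorted(b.lesion_seeds.items()):
            rois.append(grow_lesion_roi(b.flair, seed, 0.5, roi_id=lid))
        out = classify_lesions(RoiSet(rois), b.t1, b.gd_t1, mf=2.0)
        assert {r.id: r.class_code for r in out.lesions()} == b.truth_classes

    def test_lesion_outside_image_field_stays_unclassified(self):
        rois, t1, gd = _classification_setup(60, 160)
        t1_zero = t1.like(np.where(t1.data, t1.data, t1.data))
        t1_zero.data[..., 4] = 0.0  # lesion slice zeroed: out of field
        out = classify_lesions(rois, t1_zero, gd, mf=2.0)
        assert out.by_id(1).class_code == UNCLASSIFIED

    def test_nawm_overlap_flags_warning(self):
        rois, t1, gd = _classification_setup(60, 160)
        overlap = RoiSet([rois.rois[0],
                          Roi(id=1, voxels=[(0, 0, 1), (9, 9, 4)])])
        out = classify_lesions(overlap, t1, gd, mf=2.0)
        assert any("NAWM" in w for w in out.by_id(1).warnings)


class TestRoiFile:
    def _sample(self):
        return RoiSet([
            Roi(id=0, voxels=[(1, 2, 3), (1, 2, 4)], class_code=NAWM_REF,
                label_text="NAWM reference"),
            Roi(id=1, voxels=[(5, 5, 5)], class_code="C3", label_text="C3 lesion"),
            Roi(id=2, voxels=[(8, 8, 8), (8, 8, 9)], class_code="C4"),
        ])

    def test_round_trip_identity(self, tmp_path):
        path = write_roiset(self._sample(), tmp_path / "x.roi")
        back = read_roiset(path)
        for a, b in zip(self._sample(), back):
            assert (a.id, a.voxels, a.class_code, a.label_text, a.color) == \
                   (b.id, b.voxels, b.class_code, b.label_text, b.color)

    def test_manual_class_revision_round_trip(self, tmp_path):
        path = write_roiset(self._sample(), tmp_path / "x.roi")
        text = path.read_text().replace("ROI 1 C3", "ROI 1 C4")
        path.write_text(text)
        back = read_roiset(path)
        assert back.by_id(1).class_code == "C4"
        assert back.by_id(2).class_code == "C4"
        assert back.by_id(0).class_code == NAWM_REF

    def test_empty_set_round_trips(self, tmp_path):
        path = write_roiset(RoiSet([]), tmp_path / "empty.roi")
        assert len(read_roiset(path)) == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.roi"
        path.write_text("ROI 1 C1 #fff lesion\n1 2\n")
        with pytest.raises(ValueError, match=r"bad\.roi:2"):
            read_roiset(path)


class TestClassMasks:
    def test_counts_and_union(self):
        grid = _volume(np.zeros((10, 10, 10)))
        rois = RoiSet([
            Roi(id=1, voxels=[(1, 1, 1), (1, 1, 2)], class_code="C3"),
            Roi(id=2, voxels=[(5, 5, 5)], class_code="C3"),
            Roi(id=3, voxels=[(8, 8, 8)], class_code="C4"),
            Roi(id=0, voxels=[(0, 0, 0), (0, 0, 1)], class_code=NAWM_REF),
        ])
        masks = class_masks(rois, grid)
        from scipy import ndimage
        assert ndimage.label(masks["C3"].data)[1] == 2
        assert ndimage.label(masks["total"].data)[1] == 3
        assert masks["total"].data.sum() == sum(
            masks[f"lesion_{i}"].data.sum() for i in (1, 2, 3))
        union = (masks["C1"].data | masks["C2"].data
                 | masks["C3"].data | masks["C4"].data)
        np.testing.assert_array_equal(union, masks["total"].data)
        assert masks["C1"].data.sum() == 0          # emitted even when empty
        assert masks["total"].data[0, 0, 0] == 0    # NAWM excluded
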