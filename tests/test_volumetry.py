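"""Overlap differencing, cleanup emulation and relative volumetry."""

import warnings

import numpy as np
import pytest

from canalvol._exceptions import VolumetryError
from canalvol.phantom import PhantomSpec, apply_plug, generate_labyrinth, \
    generate_pair
from canalvol.segmentation import ROIBox
from canalvol.volume_io import SegmentationMask
from canalvol.volumetry import (clean_defect, overlay_difference,
                                quantify_contralateral,
                                relative_volume_change)

from .conftest import roi_box

AFF = np.diag([0.35, 0.35, 0.35, 1.0])


def _mask(data):
    return SegmentationMask(np.asarray(data, dtype=np.uint8), AFF.copy())


def test_identical_masks_give_empty_difference(noiseless_phantom):
    _, _, fluid = noiseless_phantom
    assert overlay_difference(fluid, fluid).count() == 0


def test_empty_post_gives_pre(noiseless_phantom):
    _, _, fluid = noiseless_phantom
    empty = SegmentationMask(np.zeros_like(fluid.data), fluid.affine)
    np.testing.assert_array_equal(overlay_difference(fluid, empty).data,
                                  fluid.data)


def test_grid_mismatch_rejected(noiseless_phantom):
    _, _, fluid = noiseless_phantom
    other = SegmentationMask(fluid.data.copy(), fluid.affine + 0.5)
    with pytest.raises(VolumetryError, match="grid"):
        overlay_difference(fluid, other)


def test_same_grid_plug_difference_equals_true_defect():
    """With no pose change the pre-minus-post mask difference is the true
    defect, voxel for voxel."""
    spec = PhantomSpec(noise_sd=0.0, plug_extent_deg=75.0)
    pre, fluid = generate_labyrinth(spec)
    post, true_defect, _ = apply_plug(pre, fluid, spec)
    post_mask = SegmentationMask((post.meta["_occ"] >= 0.5).astype(np.uint8),
                                 fluid.affine)
    diff = overlay_difference(fluid, post_mask)
    np.testing.assert_array_equal(diff.data, true_defect.data)
    # a voxel is never both defect and fluid-after
    assert int((diff.data & post_mask.data).sum()) == 0


def _blob_and_shell():
    """True-plug blob plus the thin spurious shell a slight
    misregistration paints over the rest of the labyrinth."""
    data = np.zeros((48, 48, 48), dtype=np.uint8)
    idx = np.indices(data.shape) - 12
    blob = (idx ** 2).sum(0) <= 4 ** 2
    idx2 = np.indices(data.shape) - 32
    r2 = (idx2 ** 2).sum(0)
    shell = (r2 <= 10 ** 2) & (r2 >= 9 ** 2)
    data[blob | shell] = 1
    return _mask(data), int(blob.sum())


def test_clean_defect_whole_grid_single_component():
    idx = np.indices((48, 48, 48)) - 12
    blob_only = _mask(((idx ** 2).sum(0) <= 4 ** 2).astype(np.uint8))
    keep = ROIBox((0, 0, 0), (48, 48, 48))
    out = clean_defect(blob_only, keep)
    np.testing.assert_array_equal(out.data, blob_only.data)


def test_clean_defect_keeps_plug_blob_only():
    m, blob_count = _blob_and_shell()
    keep = ROIBox((2, 2, 2), (24, 24, 24))  # box around the blob
    out = clean_defect(m, keep)
    assert out.count() == pytest.approx(blob_count, rel=0.02)


def test_clean_defect_disjoint_region_warns_empty():
    m, _ = _blob_and_shell()
    keep = ROIBox((40, 40, 40), (47, 47, 47))
    with pytest.warns(UserWarning, match="empty"):
        out = clean_defect(m, keep)
    assert out.count() == 0


def test_relative_volume_trivial_bounds(noiseless_phantom):
    _, _, fluid = noiseless_phantom
    empty = SegmentationMask(np.zeros_like(fluid.data), fluid.affine)
    assert relative_volume_change(empty, fluid) == 0.0
    assert relative_volume_change(fluid, fluid) == 100.0
    with pytest.raises(VolumetryError, match="empty reference"):
        relative_volume_change(fluid, empty)


def test_relative_volume_clips_to_reference(noiseless_phantom):
    _, _, fluid = noiseless_phantom
    everything = SegmentationMask(np.ones_like(fluid.data), fluid.affine)
    assert relative_volume_change(everything, fluid) == 100.0


def test_end_to_end_recovery_within_one_point(pair_5pct, result_5pct):
    truth = pair_5pct.truth["relative_defect_pct"]
    assert result_5pct.relative_defect_pct == pytest.approx(truth, abs=1.0)
    assert result_5pct.mode == "pre_post"
    assert 0.0 <= result_5pct.relative_defect_pct <= 100.0


def test_end_to_end_defect_inside_reference(result_5pct):
    ref = result_5pct.reference_mask.data.astype(bool)
    dft = result_5pct.defect_mask.data.astype(bool)
    assert np.all(ref[dft])
    assert result_5pct.defect_mm3 == pytest.approx(
        result_5pct.defect_voxels * 0.35 ** 3, abs=1e-9)


def test_end_to_end_provenance(result_5pct):
    prov = result_5pct.provenance
    assert "otsu_threshold" in prov["pre_segmentation"]
    assert "otsu_threshold" in prov["post_segmentation"]
    assert "angles_deg" in prov["transform"]


def test_contralateral_swapped_side_warns_and_reports_zero():
    """Plug accidentally attributed to the healthy ear: the mirrored
    'healthy' reference has less fluid than the 'operated' ear, so the
    defect is ~0 and the provenance carries a negative-volume warning."""
    spec = PhantomSpec.bilateral_default(plug_extent_deg=70.0, seed=13)
    pair = generate_pair(spec)
    nx = pair.post.shape[0]
    keep = pair.truth["keep_region"]
    mirrored_keep = ROIBox(
        (nx - keep["upper"][0], keep["lower"][1], keep["lower"][2]),
        (nx - keep["lower"][0], keep["upper"][1], keep["upper"][2]))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = quantify_contralateral(
            pair.post, "left", roi_box(pair.truth["rois"]["left"]),
            mirrored_keep)
    assert res.relative_defect_pct < 1.0
    assert "warning" in res.provenance
    assert any("MORE fluid" in str(w.message) for w in caught)
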