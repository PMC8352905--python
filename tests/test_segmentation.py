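"""Otsu thresholding and ROI-restricted fluid segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canalvol._exceptions import DegenerateHistogramError, SegmentationError
from canalvol.phantom import PhantomSpec, generate_labyrinth
from canalvol.segmentation import (ROIBox, keep_components, otsu_threshold,
                                   segment_fluid)
from canalvol.volume_io import SegmentationMask

from .conftest import dice, otsu_exhaustive_exact

ROI = ROIBox((4, 4, 4), (60, 60, 60))


def test_two_point_histogram_tie_break():
    """Two spikes at 10 and 200: any gap edge maximizes the between-class
    variance; the lowest candidate (first edge above 10) must win."""
    x = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)])
    res = otsu_threshold(x, nbins=256)
    first_edge = 10.0 + (200.0 - 10.0) / 256
    assert res.threshold == pytest.approx(first_edge, abs=1e-9)
    assert res.class_means == pytest.approx((10.0, 200.0), abs=1e-9)
    assert sum(res.class_weights) == pytest.approx(1.0, abs=1e-12)


def test_matches_exhaustive_oracle_random_histograms():
    rng = np.random.default_rng(11)
    for i in range(30):
        if i % 2 == 0:
            x = rng.integers(0, 256, size=rng.integers(50, 1500)).astype(float)
        else:
            x = rng.normal(rng.uniform(0, 100), rng.uniform(1, 30),
                           size=rng.integers(50, 1500))
        if x.min() == x.max():
            continue
        assert otsu_threshold(x).threshold == otsu_exhaustive_exact(x)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.integers(0, 255), min_size=5, max_size=200))
def test_matches_exhaustive_oracle_hypothesis(values):
    x = np.asarray(values, dtype=float)
    if x.min() == x.max():
        return
    assert otsu_threshold(x).threshold == otsu_exhaustive_exact(x)


def test_bimodal_gaussian_mixture_threshold_separates_modes():
    """Well-separated equal Gaussian clusters: the threshold equals the
    exhaustive oracle and falls in the empty inter-mode gap (with the
    lowest-candidate tie break, at the gap's lower edge)."""
    rng = np.random.default_rng(42)
    x = np.concatenate([rng.normal(50, 5, 2500), rng.normal(150, 5, 2500)])
    res = otsu_threshold(x)
    assert res.threshold == otsu_exhaustive_exact(x)
    assert 65.0 < res.threshold < 135.0  # above mode 1, below mode 2
    assert res.class_means[0] == pytest.approx(50.0, abs=2.0)
    assert res.class_means[1] == pytest.approx(150.0, abs=2.0)


@pytest.mark.parametrize("a,b", [(2.0, 5.0), (0.5, -3.0), (117.0, 1234.0)])
def test_affine_intensity_invariance(a, b):
    """x -> a*x + b (a > 0) maps the threshold through the same affine:
    this is what lets one ROI definition serve drifted scans."""
    rng = np.random.default_rng(1)
    x = np.concatenate([rng.normal(30, 8, 700), rng.normal(90, 10, 500)])
    t1 = otsu_threshold(x).threshold
    t2 = otsu_threshold(a * x + b).threshold
    assert t2 == pytest.approx(a * t1 + b, rel=1e-9, abs=1e-9)


def test_degenerate_inputs_rejected():
    with pytest.raises(DegenerateHistogramError, match="degenerate"):
        otsu_threshold(np.full(100, 7.0))
    with pytest.raises(DegenerateHistogramError):
        otsu_threshold(np.array([]))
    with pytest.raises(SegmentationError):
        otsu_threshold(np.array([1.0, 2.0]), nbins=1)


def test_threshold_strictly_inside_range():
    rng = np.random.default_rng(2)
    for _ in range(10):
        x = rng.normal(0, 10, 500)
        t = otsu_threshold(x).threshold
        assert x.min() < t < x.max()


def test_background_roi_raises_degenerate():
    spec = PhantomSpec(noise_sd=0.0)
    pre, _ = generate_labyrinth(spec)
    with pytest.raises(DegenerateHistogramError):
        segment_fluid(pre, ROIBox((0, 0, 0), (6, 6, 6)))


def test_noiseless_binary_phantom_segmented_exactly():
    spec = PhantomSpec(noise_sd=0.0, supersample=1)
    pre, fluid = generate_labyrinth(spec)
    mask = segment_fluid(pre, ROI)
    np.testing.assert_array_equal(mask.data, fluid.data)


def test_noiseless_partial_volume_phantom_near_exact(noiseless_phantom):
    _, pre, fluid = noiseless_phantom
    mask = segment_fluid(pre, ROI)
    assert dice(mask.data, fluid.data) > 0.99


def test_noisy_phantom_dice():
    """Noise at 10% of the fluid-background contrast still yields a high
    overlap with the true mask."""
    spec = PhantomSpec(noise_sd=9.0, seed=3)
    pre, fluid = generate_labyrinth(spec)
    mask = segment_fluid(pre, ROI)
    assert dice(mask.data, fluid.data) >= 0.90
    assert "otsu_threshold" in mask.provenance


def test_roi_validation():
    with pytest.raises(SegmentationError):
        ROIBox((4, 4, 4), (4, 10, 10))
    with pytest.raises(SegmentationError):
        ROIBox((0, 0, 0), (90, 10, 10)).validate((64, 64, 64))


def _speckled_mask():
    data = np.zeros((32, 32, 32), dtype=np.uint8)
    data[4:20, 4:20, 4:20] = 1  # big block
    for corner in ((26, 2, 2), (2, 26, 2), (2, 2, 26)):
        i, j, k = corner
        data[i:i + 2, j, k] = 1  # three 2-voxel specks
    return SegmentationMask(data, np.eye(4) * np.diag([0.35, 0.35, 0.35, 1]))


def test_keep_components_removes_specks():
    m = _speckled_mask()
    out = keep_components(m, 26, 1.0)
    assert out.count() == 16 ** 3
    assert out.provenance["components_before"] == 4
    assert out.provenance["components_after"] == 1


def test_keep_components_zero_threshold_is_identity():
    m = _speckled_mask()
    np.testing.assert_array_equal(keep_components(m, 26, 0.0).data, m.data)


def test_keep_components_single_component_unchanged(noiseless_phantom):
    _, _, fluid = noiseless_phantom
    out = keep_components(fluid, 26, 1.0)
    np.testing.assert_array_equal(out.data, fluid.data)


def test_segmented_volume_monotone_in_component_threshold():
    spec = PhantomSpec(noise_sd=13.0, seed=4)
    pre, _ = generate_labyrinth(spec)
    vols = [segment_fluid(pre, ROI, min_component_mm3=t).volume_mm3()
            for t in (0.0, 0.5, 1.0, 5.0, 20.0)]
    assert all(b <= a for a, b in zip(vols, vols[1:]))
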