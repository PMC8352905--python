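"""Ray-casting renderer: compositing math, mask restriction, geometry."""

import numpy as np
import pytest

from canalvol._exceptions import ConfigError
from canalvol.rendering import (Camera, TransferFunction, default_camera,
                                raycast, render_defect_overlay, save_png,
                                transfer_function_from_histogram, turntable)
from canalvol.volume_io import SegmentationMask, Volume


def _cube(n=32, value=100.0):
    aff = np.eye(4)
    aff[:3, 3] = -(n - 1) / 2.0
    v = Volume(np.full((n, n, n), value), aff)
    m = SegmentationMask(np.ones((n, n, n), dtype=np.uint8), aff)
    return v, m


def _axis_camera(n=32, step=1.0, size=16):
    # view straight down +z; every ray crosses the full slab of length n
    return Camera(eye=(0, 0, -3 * n), look_at=(0, 0, 0), up=(0, 1, 0),
                  image_size=(size, size), ortho_height_mm=n / 2.0,
                  step_mm=step)


def _const_tf(alpha, color=(1.0, 0.0, 0.0)):
    r, g, b = color
    return TransferFunction([[-1e6, r, g, b, alpha], [1e6, r, g, b, alpha]])


def test_transfer_function_validation():
    with pytest.raises(ConfigError):
        TransferFunction([[0, 0, 0, 0, 0], [0, 1, 1, 1, 1]])  # not increasing
    with pytest.raises(ConfigError):
        TransferFunction([[0, 0, 0, 0, 1.5]])  # alpha out of range


def test_camera_validation():
    with pytest.raises(ConfigError):
        Camera(eye=(0, 0, 0), look_at=(0, 0, 0))
    with pytest.raises(ConfigError):
        Camera(eye=(0, 0, -10), look_at=(0, 0, 0), up=(0, 0, 1))
    with pytest.raises(ConfigError):
        Camera(eye=(0, 0, -10), look_at=(0, 0, 0), step_mm=0.0)


def test_transparent_tf_gives_background_exactly():
    v, m = _cube()
    img = raycast(v, m, _const_tf(0.0), _axis_camera(),
                  background=(0.2, 0.4, 0.6))
    np.testing.assert_array_equal(img[..., 3], 0.0)
    assert np.all(img[..., 0] == 0.2)
    assert np.all(img[..., 1] == 0.4)
    assert np.all(img[..., 2] == 0.6)


@pytest.mark.parametrize("alpha,step,n_samples", [
    (0.1, 1.0, 32), (0.1, 2.0, 16), (0.05, 1.0, 32)])
def test_closed_form_compositing(alpha, step, n_samples):
    """Homogeneous in-mask slab: pixel alpha is exactly 1-(1-a)^n
    (opacities chosen to stay below the 0.99 early-termination gate)."""
    v, m = _cube(32)
    img = raycast(v, m, _const_tf(alpha), _axis_camera(step=step))
    expected = 1.0 - (1.0 - alpha) ** n_samples
    np.testing.assert_allclose(img[..., 3], expected, atol=1e-6)


def test_back_to_front_equivalence():
    """Front-to-back result agrees with the classic back-to-front
    recurrence evaluated on the same per-sample opacities."""
    v, m = _cube(32)
    alpha, n = 0.1, 32
    img = raycast(v, m, _const_tf(alpha, (0.3, 0.6, 0.9)), _axis_camera(),
                  background=(0.0, 0.0, 0.0))
    c_btf = np.zeros(3)
    for _ in range(n):  # back to front: C = a*c + (1-a)*C
        c_btf = alpha * np.array([0.3, 0.6, 0.9]) + (1 - alpha) * c_btf
    np.testing.assert_allclose(img[8, 8, :3], c_btf, atol=1e-6)


def test_alpha_monotone_in_opacity():
    v, m = _cube()
    cam = _axis_camera()
    alphas = [raycast(v, m, _const_tf(a), cam)[8, 8, 3]
              for a in (0.02, 0.05, 0.1, 0.3)]
    assert all(b > a for a, b in zip(alphas, alphas[1:]))


def test_empty_mask_blocks_everything():
    v, _ = _cube()
    m = SegmentationMask(np.zeros(v.shape, dtype=np.uint8), v.affine)
    img = raycast(v, m, _const_tf(0.9), _axis_camera(), background=(1, 1, 1))
    np.testing.assert_array_equal(img[..., 3], 0.0)
    np.testing.assert_array_equal(img[..., :3], 1.0)


def test_pixels_independent_of_out_of_mask_voxels():
    rng = np.random.default_rng(0)
    v, _ = _cube()
    idx = np.indices(v.shape) - 15.5
    sphere = ((idx ** 2).sum(0) <= 8 ** 2).astype(np.uint8)
    m = SegmentationMask(sphere, v.affine)
    tf = TransferFunction([[0, 1, 0.5, 0, 0], [200, 1, 0.5, 0, 0.4]])
    cam = _axis_camera()
    base = raycast(v, m, tf, cam)
    noisy = Volume(np.where(sphere, v.data,
                            rng.uniform(0, 1000, v.shape)), v.affine)
    fuzzed = raycast(noisy, m, tf, cam)
    np.testing.assert_array_equal(base, fuzzed)


def test_overlay_empty_defect_ignores_defect_color():
    _, m = _cube()
    empty = SegmentationMask(np.zeros(m.shape, dtype=np.uint8), m.affine)
    cam = _axis_camera()
    a = render_defect_overlay(m, empty, cam,
                              colors=((0.7, 0.7, 0.7, 0.1), (0, 0, 1, 0.9)))
    b = render_defect_overlay(m, empty, cam,
                              colors=((0.7, 0.7, 0.7, 0.1), (1, 0, 0, 0.2)))
    np.testing.assert_array_equal(a, b)


def test_overlay_full_defect_uses_only_defect_color():
    _, m = _cube()
    cam = _axis_camera()
    def_rgba = (0.1, 0.2, 0.9, 0.5)
    img = render_defect_overlay(m, m, cam,
                                colors=((0.7, 0.7, 0.7, 0.1), def_rgba),
                                background=(0.0, 0.0, 0.0))
    covered = img[..., 3] > 0.5
    assert covered.any()
    a = img[covered][:, 3]
    for ch in range(3):
        np.testing.assert_allclose(img[covered][:, ch], a * def_rgba[ch],
                                   atol=1e-9)


def test_defect_pixel_centroid_matches_projection(pair_5pct):
    """Defect-colored pixels center on the orthographic projection of the
    true defect's world centroid."""
    lab, dft = pair_5pct.true_fluid, pair_5pct.true_defect
    cam = default_camera(lab, image_size=(128, 128))
    base = render_defect_overlay(
        lab, SegmentationMask(np.zeros_like(dft.data), dft.affine), cam)
    img = render_defect_overlay(lab, dft, cam)
    changed = np.any(np.abs(img - base) > 1e-6, axis=-1)
    assert changed.any()
    rows, cols = np.nonzero(changed)
    # project true centroid through the camera
    ivox = np.argwhere(dft.data)
    world = ivox @ dft.affine[:3, :3].T + dft.affine[:3, 3]
    centroid = world.mean(axis=0)
    f, r, u = cam.basis()
    w, h = cam.image_size
    height = cam.ortho_height_mm
    width = height * w / h
    rel = centroid - np.asarray(cam.eye)
    col = (np.dot(rel, r) / width + 0.5) * w - 0.5
    row = (0.5 - np.dot(rel, u) / height) * h - 0.5
    assert abs(cols.mean() - col) < 5.0
    assert abs(rows.mean() - row) < 5.0


def test_turntable_single_frame_matches_overlay():
    _, m = _cube()
    empty = SegmentationMask(np.zeros(m.shape, dtype=np.uint8), m.affine)
    cam = _axis_camera()
    frames = turntable((m, empty), cam, 1)
    assert len(frames) == 1
    np.testing.assert_array_equal(frames[0],
                                  render_defect_overlay(m, empty, cam))


def test_turntable_invariant_for_axis_symmetric_sphere():
    n = 48
    aff = np.eye(4)
    aff[:3, 3] = -(n - 1) / 2.0
    idx = np.indices((n, n, n)) - (n - 1) / 2.0
    sphere = ((idx ** 2).sum(0) <= 12 ** 2).astype(np.uint8)
    m = SegmentationMask(sphere, aff)
    empty = SegmentationMask(np.zeros_like(sphere), aff)
    cam = Camera(eye=(40, 0, 0), look_at=(0, 0, 0), up=(0, 0, 1),
                 image_size=(64, 64), ortho_height_mm=40, step_mm=0.5)
    frames = turntable((m, empty), cam, 4)
    for f in frames[1:]:
        np.testing.assert_allclose(f, frames[0], atol=0.02)


def test_turntable_rejects_zero_frames():
    _, m = _cube()
    with pytest.raises(ConfigError):
        turntable((m, m), _axis_camera(), 0)


def test_histogram_transfer_function(noiseless_phantom):
    _, pre, fluid = noiseless_phantom
    tf = transfer_function_from_histogram(pre, fluid)
    # fully transparent at background, opaque-ish at fluid intensity
    assert tf(np.array([10.0]))[0, 3] == 0.0
    assert tf(np.array([100.0]))[0, 3] > 0.2


def test_save_png_round_trip(tmp_path):
    from PIL import Image
    img = np.zeros((8, 8, 4))
    img[2:6, 2:6] = (0.5, 0.25, 1.0, 1.0)
    p = tmp_path / "x.png"
    save_png(img, p)
    back = np.asarray(Image.open(p))
    assert back.shape == (8, 8, 4)
    assert back[4, 4, 2] == 255
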