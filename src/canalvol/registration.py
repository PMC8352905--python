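"""Rigid alignment of the post-operative scan to the pre-operative scan.

A :class:`RigidTransform` is a 6-DOF world-space map p' = R(p - c) + c + t
with R parameterized by intrinsic Euler angles (X, then Y, then Z, degrees)
about a stated center c.  ``register_rigid`` maximizes normalized
cross-correlation over the overlap region with a coarse-to-fine pyramid and
a derivative-free (Powell) search at each level: NCC is invariant to the
gain/offset intensity drift expected between two T2 acquisitions of the
same subject, so no histogram matching is needed before alignment.

``mirror_lr`` provides the contralateral mode used when no pre-operative
scan exists: the volume is reflected across the mid-sagittal plane of its
own field of view so the healthy labyrinth can stand in as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path
import warnings

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from ._exceptions import RegistrationError
from .volume_io import SegmentationMask, Volume

__all__ = ["RigidTransform", "apply_transform", "register_rigid", "mirror_lr"]

EULER_CONVENTION = "XYZ"  # intrinsic rotations, degrees


@dataclass
class RigidTransform:
    """6-DOF rotation + translation in world mm, p' = R(p - c) + c + t."""

    angles_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        self.center_mm = np.asarray(self.center_mm, dtype=float)

    @property
    def rotation(self) -> np.ndarray:
        return Rotation.from_euler(
            EULER_CONVENTION, self.angles_deg, degrees=True).as_matrix()

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-to-world map."""
        m = np.eye(4)
        r = self.rotation
        m[:3, :3] = r
        m[:3, 3] = self.center_mm + self.translation_mm - r @ self.center_mm
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray,
                    center_mm: np.ndarray | None = None) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        r = m[:3, :3]
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise RegistrationError("matrix is not a proper rotation")
        c = np.zeros(3) if center_mm is None else np.asarray(center_mm, float)
        angles = Rotation.from_matrix(r).as_euler(EULER_CONVENTION, degrees=True)
        t = m[:3, 3] - c + r @ c
        return cls(angles, t, c)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other (apply ``other`` first)."""
        return RigidTransform.from_matrix(self.matrix @ other.matrix,
                                          self.center_mm)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix),
                                          self.center_mm)

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix, np.eye(4), atol=atol))

    def to_dict(self) -> dict:
        return {
            "angles_deg": self.angles_deg.tolist(),
            "translation_mm": self.translation_mm.tolist(),
            "center_mm": self.center_mm.tolist(),
            "convention": f"intrinsic {EULER_CONVENTION}, about center_mm",
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["angles_deg"]),
                   np.asarray(d["translation_mm"]),
                   np.asarray(d.get("center_mm", (0, 0, 0))))


def _histogram_mode(data: np.ndarray) -> float:
    """Most common intensity (256-bin histogram) — background estimate."""
    counts, edges = np.histogram(data.ravel(), bins=256)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def apply_transform(
    v: Volume | SegmentationMask,
    t: RigidTransform,
    mode: str = "trilinear",
    fixed_grid: Volume | SegmentationMask | None = None,
    fill: float | None = None,
) -> Volume | SegmentationMask:
    """Resample ``v`` through ``t`` onto ``fixed_grid`` (default: own grid).

    ``t`` maps moving-world to fixed-world; each fixed voxel center w is
    filled with ``v`` sampled at t^{-1}(w).  Masks always use nearest
    neighbour; intensity volumes default to trilinear.  Out-of-field voxels
    take ``fill`` (default: histogram-mode background estimate; 0 for masks).
    """
    is_mask = isinstance(v, SegmentationMask)
    order = 0 if (is_mask or mode == "nearest") else 1
    grid = v if fixed_grid is None else fixed_grid
    m_world = np.linalg.inv(t.matrix)
    m = np.linalg.inv(v.affine) @ m_world @ grid.affine
    if fill is None:
        fill = 0.0 if is_mask else _histogram_mode(np.asarray(v.data))
    out = ndimage.affine_transform(
        np.asarray(v.data, dtype=float), m[:3, :3], m[:3, 3],
        output_shape=grid.shape, order=order, mode="constant", cval=fill)
    if is_mask:
        return SegmentationMask(out.astype(np.uint8), np.asarray(grid.affine).copy(),
                                dict(v.provenance))
    return Volume(out, np.asarray(grid.affine).copy(), dict(v.meta))


def _downsample(v: Volume, factor: int) -> Volume:
    """Anti-aliased 2^k decimation; affine rescaled, origin kept."""
    if factor == 1:
        return v
    sm = ndimage.gaussian_filter(np.asarray(v.data, float), sigma=0.5 * factor)
    data = sm[::factor, ::factor, ::factor]
    aff = v.affine.copy()
    aff[:3, :3] *= factor
    return Volume(data, aff)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def ncc_metric(fixed: Volume, moving: Volume, t: RigidTransform) -> float:
    """Normalized cross-correlation of ``moving`` resampled onto ``fixed``.

    Out-of-field samples are excluded; fewer than 5% overlapping voxels
    raises (the metric is undefined without a common field of view).
    """
    resampled = apply_transform(moving, t, fixed_grid=fixed, fill=np.nan)
    valid = ~np.isnan(resampled.data)
    n = int(valid.sum())
    if n < 0.05 * valid.size:
        raise RegistrationError("volumes do not overlap under this transform")
    return _ncc(np.asarray(fixed.data, float)[valid], resampled.data[valid])


def register_rigid(
    fixed: Volume,
    moving: Volume,
    init: RigidTransform | None = None,
    levels: int = 3,
) -> RigidTransform:
    """Recover the rigid transform aligning ``moving`` onto ``fixed``.

    Multi-resolution (x2 per level) NCC maximization with Powell's method;
    rotation center is the fixed volume's grid center.  The returned
    transform never scores below ``init`` (best-so-far is kept).  Both
    inputs must share voxel spacing — resample first.
    """
    if not np.allclose(fixed.spacing, moving.spacing, atol=1e-6):
        raise RegistrationError(
            "fixed and moving spacing differ; resample_to_spacing first")
    center = fixed.world_center()
    if init is None:
        init = RigidTransform(center_mm=center)
    params = np.concatenate([init.angles_deg, init.translation_mm])

    converged = True
    for level in range(levels - 1, -1, -1):
        factor = 2 ** level
        f_l = _downsample(fixed, factor)
        m_l = _downsample(moving, factor)

        def cost(p: np.ndarray) -> float:
            t = RigidTransform(p[:3], p[3:], center)
            try:
                return -ncc_metric(f_l, m_l, t)
            except RegistrationError:
                return 1.0  # worse than any correlation

        res = optimize.minimize(
            cost, params, method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-7, "maxiter": 60})
        params = res.x
        converged = converged and bool(res.success)

    final = RigidTransform(params[:3], params[3:], center)
    # monotone acceptance: never return something worse than the init
    score_final = ncc_metric(fixed, moving, final)
    score_init = ncc_metric(fixed, moving, init)
    if score_final < score_init:
        warnings.warn("registration did not improve on the initial transform;"
                      " returning init", stacklevel=2)
        return init
    if not converged:
        warnings.warn("registration search did not fully converge; "
                      "returning best-so-far transform", stacklevel=2)
    return final


def mirror_lr(v: Volume | SegmentationMask, axis: int | None = None
              ) -> Volume | SegmentationMask:
    """Reflect across the mid-sagittal plane of the volume's own grid.

    The data array is flipped along the left-right grid axis.  For an
    axis-aligned affine, flipping about the grid's mid-plane while keeping
    the affine is exactly the negation of world L-R coordinates about the
    field-of-view center, and makes ``mirror_lr(mirror_lr(v))`` bit-exact.
    ``axis`` overrides the orientation-label lookup for unlabeled grids.
    """
    if axis is None:
        if isinstance(v, SegmentationMask):
            axis = Volume(v.data.astype(float), v.affine).lr_axis()
        else:
            axis = v.lr_axis()
    data = np.flip(np.asarray(v.data), axis=axis).copy()
    if isinstance(v, SegmentationMask):
        return SegmentationMask(data, v.affine.copy(), dict(v.provenance))
    return Volume(data, v.affine.copy(), dict(v.meta))
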