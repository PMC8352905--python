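"""Volumes, masks and the grid/world coordinate contract.

Every image in the pipeline is a :class:`Volume`: a 3D scalar grid plus a
4x4 voxel-index -> world-mm affine.  Voxel indices are 0-based and the
affine maps voxel *centers* (the NIfTI convention); all registration math
happens in world millimetres.  Per-axis voxel size in mm is recovered from
the column norms of the affine's linear part.

Binary segmentations ride on the same grid as their parent volume and are
stored (and written to disk) as unsigned 8-bit 0/1 arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
from scipy import ndimage

from ._exceptions import VolumeIOError

__all__ = [
    "Volume",
    "SegmentationMask",
    "read_volume",
    "write_volume",
    "resample_to_spacing",
    "voxel_volume",
]


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and world affine.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    affine:
        4x4 voxel-index -> world-mm map (maps voxel centers).
    meta:
        Free-form metadata (phantom ground truth, provenance, landmarks).
        Never persisted inside the NIfTI file itself.
    """

    data: np.ndarray
    affine: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise VolumeIOError(
                f"expected 3D volume, got {self.data.ndim}D array"
            )
        if self.affine.shape != (4, 4):
            raise VolumeIOError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise VolumeIOError("affine is singular (zero/negative pixdim?)")
        if np.any(self.spacing <= 0):
            raise VolumeIOError(
                f"non-positive voxel spacing {tuple(self.spacing)} (pixdim)"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def direction(self) -> np.ndarray:
        """Unit direction cosines (linear part with spacing divided out)."""
        return self.affine[:3, :3] / self.spacing

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_center(self) -> np.ndarray:
        """World coordinate of the grid center (rotation pivot)."""
        return self.voxel_to_world((np.asarray(self.shape) - 1) / 2.0)

    def lr_axis(self) -> int:
        """Grid axis carrying the subject left-right direction.

        Decided from the affine's direction cosines (nibabel axis codes).
        Raises if the L-R world axis is oblique to every grid axis.
        """
        codes = nib.orientations.aff2axcodes(self.affine)
        for ax, code in enumerate(codes):
            if code in ("L", "R"):
                # demand near-alignment, else the flip is not a mirror
                if abs(self.direction[0, ax]) < 0.99:
                    raise VolumeIOError(
                        "left-right axis is oblique to the grid; pass an "
                        "explicit axis"
                    )
                return ax
        raise VolumeIOError("could not identify a left-right axis")

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy(), dict(self.meta))


@dataclass
class SegmentationMask:
    """Binary mask on the grid of a parent :class:`Volume` (values 0/1)."""

    data: np.ndarray
    affine: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise VolumeIOError("mask must be 3D")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise VolumeIOError("mask values must be exactly 0 or 1")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)

    @classmethod
    def from_parent(cls, parent: Volume, data: np.ndarray,
                    provenance: dict[str, Any] | None = None) -> "SegmentationMask":
        data = np.asarray(data)
        if data.shape != parent.shape:
            raise VolumeIOError("mask shape does not match parent volume")
        return cls(data.astype(np.uint8), parent.affine.copy(),
                   provenance or {})

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        return self.count() * float(np.prod(self.spacing))

    def same_grid(self, other: "SegmentationMask | Volume") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.affine, other.affine, atol=1e-6))


def read_volume(path: str | Path) -> Volume:
    """Load a NIfTI file as a :class:`Volume`.

    Spacing is taken from the affine; the header pixdim is cross-checked and
    a zero/negative pixdim is a hard error naming the field.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeIOError(f"could not parse {path} as NIfTI: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(
            f"expected 3D volume, got {data.ndim}D image in {path}"
        )
    pixdim = img.header["pixdim"][1:4]
    if np.any(pixdim <= 0):
        raise VolumeIOError(
            f"header field pixdim has non-positive entries {tuple(pixdim)}"
        )
    return Volume(np.asarray(data, dtype=np.float64), np.asarray(img.affine))


def read_mask(path: str | Path) -> SegmentationMask:
    """Load a NIfTI binary mask; any nonzero voxel counts as foreground."""
    v = read_volume(path)
    return SegmentationMask((v.data > 0).astype(np.uint8), v.affine)


def write_volume(v: Volume | SegmentationMask, path: str | Path) -> None:
    """Write to NIfTI preserving affine; masks go out as unsigned 8-bit."""
    path = Path(path)
    if not path.parent.exists():
        raise VolumeIOError(f"directory does not exist: {path.parent}")
    if isinstance(v, SegmentationMask):
        data = v.data.astype(np.uint8)
    else:
        data = np.asarray(v.data)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_zooms(tuple(np.linalg.norm(v.affine[:3, :3], axis=0)))
    nib.save(img, str(path))


def voxel_volume(v: Volume | SegmentationMask) -> float:
    """mm^3 per voxel: the product of the spacing components."""
    return float(np.prod(v.spacing))


def resample_to_spacing(
    v: Volume | SegmentationMask,
    target_spacing: tuple[float, float, float] | np.ndarray,
    mode: str = "trilinear",
) -> Volume | SegmentationMask:
    """Resample onto an equally-oriented grid with the given spacing.

    The world position of the first voxel center and the direction cosines
    are kept; the output grid size is chosen to preserve the world extent
    within one voxel.  ``trilinear`` is for intensities, ``nearest`` for
    masks (masks always go through nearest regardless of ``mode`` to keep
    binarity).
    """
    ts = np.asarray(target_spacing, dtype=float)
    if ts.shape != (3,) or np.any(ts <= 0):
        raise VolumeIOError(f"target spacing must be 3 positive values, got {ts}")
    is_mask = isinstance(v, SegmentationMask)
    order = 0 if (is_mask or mode == "nearest") else 1
    if mode not in ("trilinear", "nearest"):
        raise VolumeIOError(f"unknown interpolation mode {mode!r}")
    sp = v.spacing
    if np.allclose(sp, ts, atol=1e-9):
        out = v.copy() if isinstance(v, Volume) else SegmentationMask(
            v.data.copy(), v.affine.copy())
        return out
    new_shape = np.maximum(
        1, np.round(np.asarray(v.shape) * sp / ts)).astype(int)
    direction = v.affine[:3, :3] / sp
    new_affine = np.eye(4)
    new_affine[:3, :3] = direction * ts
    new_affine[:3, 3] = v.affine[:3, 3]
    # output voxel index -> input voxel index
    m = np.linalg.inv(v.affine) @ new_affine
    data = ndimage.affine_transform(
        np.asarray(v.data, dtype=float), m[:3, :3], m[:3, 3],
        output_shape=tuple(new_shape), order=order, mode="nearest")
    if is_mask:
        return SegmentationMask(data.astype(np.uint8), new_affine,
                                dict(v.provenance))
    return Volume(data, new_affine, dict(v.meta))
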