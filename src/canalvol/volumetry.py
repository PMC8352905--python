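"""Filling-defect extraction and relative volume quantification.

The primary output is the relative volume of the filling defect: the set
of voxels carrying labyrinth fluid signal before surgery but not after,
expressed as a percent of the pre-operative labyrinth fluid volume.  A
relative (not absolute-mm^3) figure is used deliberately: the two scans
differ in resolution and quality, so an absolute pre/post comparison is
not trustworthy, while a within-scan ratio is.

Because the two segmented surfaces never match perfectly, the raw
pre-AND-NOT-post difference contains a thin spurious shell over the whole
labyrinth.  The manual cleanup of that shell is emulated deterministically:
the difference is intersected with a declared keep-region (a box or mask
around the expected plugging site), components below a physical size
threshold are dropped, and by default the largest remaining component is
taken as the defect.  Every parameter of this emulation is logged.

``quantify_contralateral`` covers patients without a pre-operative scan:
the scan is mirrored across the mid-sagittal plane, the mirrored healthy
labyrinth is rigidly aligned onto the operated one and serves as the
reference anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any
import warnings

import numpy as np

from ._exceptions import VolumetryError
from .registration import (RigidTransform, apply_transform, mirror_lr,
                           register_rigid)
from .segmentation import ROIBox, keep_components, largest_component, \
    segment_fluid
from .volume_io import (SegmentationMask, Volume, resample_to_spacing,
                        voxel_volume)

__all__ = [
    "DefectResult",
    "PipelineParams",
    "overlay_difference",
    "clean_defect",
    "relative_volume_change",
    "quantify_pre_post",
    "quantify_contralateral",
]

MIN_PIPELINE_DIM = 8


@dataclass(frozen=True)
class PipelineParams:
    """Tunable stage parameters with the pipeline defaults."""

    min_component_mm3: float = 1.0
    connectivity: int = 26
    keep_largest: bool = True
    registration_levels: int = 3
    bright_foreground: bool = True


@dataclass
class DefectResult:
    """Quantified filling defect with full provenance."""

    defect_voxels: int
    defect_mm3: float
    reference_mm3: float
    relative_defect_pct: float
    mode: str  # "pre_post" | "contralateral"
    cleanup_applied: bool
    defect_mask: SegmentationMask
    reference_mask: SegmentationMask
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_defect_pct <= 100.0):
            raise VolumetryError("relative defect must lie in [0, 100]%")

    def to_dict(self) -> dict[str, Any]:
        return {
            "defect_voxels": self.defect_voxels,
            "defect_mm3": self.defect_mm3,
            "reference_mm3": self.reference_mm3,
            "relative_defect_pct": self.relative_defect_pct,
            "mode": self.mode,
            "cleanup_applied": self.cleanup_applied,
            "provenance": self.provenance,
        }


def overlay_difference(pre_mask: SegmentationMask,
                       post_mask: SegmentationMask) -> SegmentationMask:
    """Voxels with fluid before but not after: pre AND NOT post."""
    if not pre_mask.same_grid(post_mask):
        raise VolumetryError("pre/post masks are not on the same grid; "
                             "transform the post mask first")
    diff = (pre_mask.data.astype(bool)
            & ~post_mask.data.astype(bool)).astype(np.uint8)
    return SegmentationMask(diff, pre_mask.affine.copy())


def clean_defect(
    diff: SegmentationMask,
    keep_region: ROIBox | SegmentationMask,
    connectivity: int = 26,
    min_component_mm3: float = 1.0,
    keep_largest: bool = True,
) -> SegmentationMask:
    """Deterministic emulation of the manual removal of spurious voxels.

    Intersect with the keep-region, drop components below the physical
    size threshold, optionally keep only the largest component.  Warns if
    nothing survives (plugging failure or a misplaced region).
    """
    if isinstance(keep_region, ROIBox):
        keep_region.validate(diff.shape)
        region = np.zeros(diff.shape, dtype=bool)
        region[keep_region.slices()] = True
    else:
        if not diff.same_grid(keep_region):
            raise VolumetryError("keep-region grid does not match difference")
        region = keep_region.data.astype(bool)
    out = SegmentationMask((diff.data.astype(bool) & region).astype(np.uint8),
                           diff.affine.copy(), dict(diff.provenance))
    out = keep_components(out, connectivity, min_component_mm3)
    if keep_largest:
        out = largest_component(out, connectivity)
    if out.count() == 0:
        warnings.warn("cleaned defect is empty: either plugging failed or "
                      "the keep-region misses the defect", stacklevel=2)
    return out


def relative_volume_change(defect: SegmentationMask,
                           reference: SegmentationMask) -> float:
    """100 * |defect| / |reference|, with defect clipped into reference."""
    if not defect.same_grid(reference):
        raise VolumetryError("defect and reference masks on different grids")
    ref_n = reference.count()
    if ref_n == 0:
        raise VolumetryError("empty reference labyrinth mask")
    inter = int((defect.data.astype(bool)
                 & reference.data.astype(bool)).sum())
    return 100.0 * inter / ref_n


def _check_pipeline_volume(v: Volume, name: str) -> None:
    if min(v.shape) < MIN_PIPELINE_DIM:
        raise VolumetryError(
            f"{name} volume too small for the pipeline "
            f"(every axis must have >= {MIN_PIPELINE_DIM} voxels)")


def _harmonize(pre: Volume, post: Volume) -> tuple[Volume, dict]:
    """Resample the lower-resolution scan up to the finer spacing.

    The pre scan is the fixed grid throughout, so when spacings differ the
    post scan is brought to the pre scan's spacing (upsampling preserves
    the thin canal signal; the defect is always measured on the pre grid).
    """
    log: dict[str, Any] = {"resampled": False}
    if not np.allclose(pre.spacing, post.spacing, atol=1e-6):
        post = resample_to_spacing(post, tuple(pre.spacing), "trilinear")
        log = {"resampled": True, "target_spacing": pre.spacing.tolist()}
    return post, log


def quantify_pre_post(
    pre: Volume,
    post: Volume,
    roi: ROIBox | SegmentationMask,
    keep_region: ROIBox | SegmentationMask,
    params: PipelineParams = PipelineParams(),
    init_transform: RigidTransform | None = None,
) -> DefectResult:
    """Full pre/post workflow: resample, register, segment, difference,
    clean, and report the relative defect.

    The pre scan is the fixed grid; the post scan is resampled to its
    spacing, rigidly registered onto it, both are Otsu-segmented inside
    the same ROI, and the cleaned pre-minus-post difference is reported
    relative to the pre-operative labyrinth volume.
    """
    _check_pipeline_volume(pre, "pre")
    _check_pipeline_volume(post, "post")
    post_rs, resample_log = _harmonize(pre, post)
    transform = register_rigid(pre, post_rs, init=init_transform,
                               levels=params.registration_levels)
    post_on_pre = apply_transform(post_rs, transform, "trilinear",
                                  fixed_grid=pre)
    pre_mask = segment_fluid(pre, roi, params.min_component_mm3,
                             params.connectivity, params.bright_foreground)
    post_mask = segment_fluid(post_on_pre, roi, params.min_component_mm3,
                              params.connectivity, params.bright_foreground)
    diff = overlay_difference(pre_mask, post_mask)
    defect = clean_defect(diff, keep_region, params.connectivity,
                          params.min_component_mm3, params.keep_largest)
    rel = relative_volume_change(defect, pre_mask)
    vox = voxel_volume(pre)
    return DefectResult(
        defect_voxels=defect.count(),
        defect_mm3=defect.count() * vox,
        reference_mm3=pre_mask.count() * vox,
        relative_defect_pct=rel,
        mode="pre_post",
        cleanup_applied=True,
        defect_mask=defect,
        reference_mask=pre_mask,
        provenance={
            "resample": resample_log,
            "transform": transform.to_dict(),
            "pre_segmentation": pre_mask.provenance,
            "post_segmentation": post_mask.provenance,
            "raw_difference_voxels": diff.count(),
            "params": params.__dict__,
        },
    )


def quantify_contralateral(
    post: Volume,
    operated_side: str,
    roi_operated: ROIBox | SegmentationMask,
    keep_region: ROIBox | SegmentationMask,
    params: PipelineParams = PipelineParams(),
    lr_axis: int | None = None,
) -> DefectResult:
    """Mirror-flip workflow for patients without a pre-operative scan.

    The scan is reflected across its mid-sagittal plane, registered back
    onto itself (correcting head asymmetry), and the mirrored healthy
    labyrinth plays the role of the pre-operative reference: the defect is
    mirrored-healthy AND NOT operated, cleaned and reported relative to
    the mirrored healthy labyrinth volume.
    """
    if operated_side not in ("left", "right"):
        raise VolumetryError("operated side must be 'left' or 'right'")
    _check_pipeline_volume(post, "post")
    mirrored = mirror_lr(post, axis=lr_axis)
    transform = register_rigid(post, mirrored,
                               levels=params.registration_levels)
    mirrored_on = apply_transform(mirrored, transform, "trilinear",
                                  fixed_grid=post)
    operated_mask = segment_fluid(post, roi_operated,
                                  params.min_component_mm3,
                                  params.connectivity,
                                  params.bright_foreground)
    healthy_mask = segment_fluid(mirrored_on, roi_operated,
                                 params.min_component_mm3,
                                 params.connectivity,
                                 params.bright_foreground)
    diff = overlay_difference(healthy_mask, operated_mask)
    defect = clean_defect(diff, keep_region, params.connectivity,
                          params.min_component_mm3, params.keep_largest)
    rel = relative_volume_change(defect, healthy_mask)
    reverse = overlay_difference(operated_mask, healthy_mask)
    provenance: dict[str, Any] = {
        "transform": transform.to_dict(),
        "operated_segmentation": operated_mask.provenance,
        "healthy_segmentation": healthy_mask.provenance,
        "raw_difference_voxels": diff.count(),
        "reverse_difference_voxels": reverse.count(),
        "params": params.__dict__,
        "operated_side": operated_side,
    }
    if reverse.count() > diff.count():
        provenance["warning"] = (
            "negative volume difference: the operated side holds MORE fluid "
            "than the mirrored healthy side — check the side assignment")
        warnings.warn(provenance["warning"], stacklevel=2)
    vox = voxel_volume(post)
    return DefectResult(
        defect_voxels=defect.count(),
        defect_mm3=defect.count() * vox,
        reference_mm3=healthy_mask.count() * vox,
        relative_defect_pct=rel,
        mode="contralateral",
        cleanup_applied=True,
        defect_mask=defect,
        reference_mask=healthy_mask,
        provenance=provenance,
    )
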