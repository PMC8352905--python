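"""Semi-automatic labyrinth fluid segmentation.

The perilymph/endolymph signal is bright on heavily T2-weighted images but
its absolute intensity drifts between acquisitions, so a fixed threshold
cannot be shared between the pre- and post-operative scan.  Instead a
region of interest containing the vestibular structure is declared, and
Otsu's threshold — the bin edge maximizing between-class variance
w0*w1*(mu0-mu1)^2, equivalently minimizing intra-class variance — is
computed from the ROI histogram of each scan independently.  Because the
histogram range is re-derived from the data, the chosen bin index is
invariant under any positive affine intensity map, which is exactly why
this copes with inter-scan intensity drift.

Small connected components are then discarded on a physical (mm^3) scale
so the result does not depend on voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path
import warnings

import numpy as np
from scipy import ndimage

from ._exceptions import DegenerateHistogramError, SegmentationError
from .volume_io import SegmentationMask, Volume, voxel_volume

__all__ = [
    "ROIBox",
    "OtsuResult",
    "otsu_threshold",
    "segment_fluid",
    "keep_components",
]


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned half-open voxel-index box [lower, upper)."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo, up = np.asarray(self.lower), np.asarray(self.upper)
        if lo.shape != (3,) or up.shape != (3,):
            raise SegmentationError("ROI corners must be 3-vectors")
        if np.any(lo >= up):
            raise SegmentationError(f"ROI lower {self.lower} must be < upper "
                                    f"{self.upper} on every axis")
        if np.any(lo < 0):
            raise SegmentationError("ROI lower corner out of bounds")

    def validate(self, shape: tuple[int, ...]) -> None:
        if np.any(np.asarray(self.upper) > np.asarray(shape)):
            raise SegmentationError(
                f"ROI {self.upper} exceeds grid bounds {shape}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, up) for lo, up in zip(self.lower, self.upper))

    def to_mask(self, parent: Volume) -> SegmentationMask:
        self.validate(parent.shape)
        data = np.zeros(parent.shape, dtype=np.uint8)
        data[self.slices()] = 1
        return SegmentationMask.from_parent(parent, data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"lower": list(self.lower), "upper": list(self.upper)}))

    @classmethod
    def from_json(cls, path: str | Path) -> "ROIBox":
        d = json.loads(Path(path).read_text())
        return cls(tuple(d["lower"]), tuple(d["upper"]))


@dataclass(frozen=True)
class OtsuResult:
    """Threshold plus the class statistics at the optimum."""

    threshold: float
    between_class_variance: float
    class_means: tuple[float, float]
    class_weights: tuple[float, float]
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        w0, w1 = self.class_weights
        if abs(w0 + w1 - 1.0) > 1e-9:
            raise SegmentationError("class weights must sum to 1")


def otsu_threshold(intensities: np.ndarray, nbins: int = 256) -> OtsuResult:
    """Otsu's threshold over ``nbins`` equal-width bins of the data range.

    Candidates are the interior bin edges; the lowest maximizer of the
    between-class variance is returned (deterministic tie-break).  Raises
    :class:`DegenerateHistogramError` when the input carries no contrast
    (an ROI containing no structure).
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size == 0:
        raise DegenerateHistogramError("empty intensity collection")
    if nbins < 2:
        raise SegmentationError("nbins must be >= 2")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise DegenerateHistogramError(
            "degenerate histogram: constant intensities in region")
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "degenerate histogram: a single occupied bin")
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = counts / counts.sum()

    # cumulative class stats; candidate k puts bins [0..k] in class 0.
    # sigma_b = w0*w1*(mu0-mu1)^2 is evaluated in the cancellation-free
    # form (c - w0*G)^2 / (w0*(1-w0)) so near-tied candidates rank stably.
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    cummean = np.cumsum(p * centers)[:-1]
    grand = float((p * centers).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = np.where(
            (w0 > 0) & (w1 > 0),
            (cummean - w0 * grand) ** 2 / (w0 * w1), 0.0)
        mu0 = np.where(w0 > 0, cummean / w0, 0.0)
        mu1 = np.where(w1 > 0, (grand - cummean) / w1, 0.0)
    k = int(np.argmax(sigma_b))  # first maximum -> lowest candidate
    thr = float(edges[k + 1])
    # class stats reported from the actual samples (not bin centers)
    low = x <= thr
    return OtsuResult(
        threshold=thr,
        between_class_variance=float(sigma_b[k]),
        class_means=(float(x[low].mean()), float(x[~low].mean())),
        class_weights=(float(low.mean()), float(1.0 - low.mean())),
        bin_edges=edges,
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def keep_components(
    m: SegmentationMask,
    connectivity: int = 26,
    min_component_mm3: float = 1.0,
) -> SegmentationMask:
    """Drop connected components smaller than ``min_component_mm3``."""
    if connectivity not in _STRUCTURES:
        raise SegmentationError(f"connectivity must be 6/18/26, got {connectivity}")
    if min_component_mm3 <= 0:
        return SegmentationMask(m.data.copy(), m.affine.copy(),
                                dict(m.provenance))
    labels, n = ndimage.label(m.data, structure=_STRUCTURES[connectivity])
    if n == 0:
        return SegmentationMask(m.data.copy(), m.affine.copy(),
                                dict(m.provenance))
    sizes = np.bincount(labels.ravel())
    min_vox = min_component_mm3 / voxel_volume(m)
    keep = sizes >= min_vox
    keep[0] = False
    out = keep[labels].astype(np.uint8)
    prov = dict(m.provenance)
    prov["components_before"] = int(n)
    prov["components_after"] = int(np.count_nonzero(keep))
    return SegmentationMask(out, m.affine.copy(), prov)


def largest_component(m: SegmentationMask,
                      connectivity: int = 26) -> SegmentationMask:
    """Keep only the largest connected component (empty stays empty)."""
    labels, n = ndimage.label(m.data, structure=_STRUCTURES[connectivity])
    if n == 0:
        return SegmentationMask(m.data.copy(), m.affine.copy(),
                                dict(m.provenance))
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    out = (labels == int(np.argmax(sizes))).astype(np.uint8)
    return SegmentationMask(out, m.affine.copy(), dict(m.provenance))


def segment_fluid(
    v: Volume,
    roi: ROIBox | SegmentationMask,
    min_component_mm3: float = 1.0,
    connectivity: int = 26,
    bright_foreground: bool = True,
) -> SegmentationMask:
    """Otsu-threshold the fluid signal inside a region of interest.

    Voxels inside ``roi`` brighter than the Otsu threshold of the ROI
    histogram form the foreground (``bright_foreground=False`` inverts for
    dark-fluid modalities); everything outside the ROI is background, and
    components below ``min_component_mm3`` are removed.  The threshold and
    component counts are recorded in the mask's provenance.
    """
    if isinstance(roi, ROIBox):
        roi.validate(v.shape)
        region = roi.to_mask(v).data.astype(bool)
        roi_desc = {"lower": list(roi.lower), "upper": list(roi.upper)}
    else:
        if not roi.same_grid(v):
            raise SegmentationError("ROI mask grid does not match volume")
        region = roi.data.astype(bool)
        roi_desc = {"mask_voxels": int(region.sum())}
    vals = np.asarray(v.data)[region]
    res = otsu_threshold(vals)
    if bright_foreground:
        fg = np.asarray(v.data) > res.threshold
    else:
        fg = np.asarray(v.data) < res.threshold
    data = (fg & region).astype(np.uint8)
    mask = SegmentationMask.from_parent(
        v, data, provenance={
            "otsu_threshold": res.threshold,
            "between_class_variance": res.between_class_variance,
            "class_means": list(res.class_means),
            "roi": roi_desc,
            "bright_foreground": bright_foreground,
            "min_component_mm3": min_component_mm3,
            "connectivity": connectivity,
        })
    mask = keep_components(mask, connectivity, min_component_mm3)
    if mask.count() == 0:
        warnings.warn("segmentation produced an empty mask", stacklevel=2)
    return mask
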