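"""Exception hierarchy; the CLI maps these to distinct exit codes."""


class CanalvolError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(CanalvolError):
    """Invalid run configuration (unknown keys, bad values)."""


class VolumeIOError(CanalvolError):
    """File missing/unreadable, bad header, grid-contract violations."""


class SegmentationError(CanalvolError):
    """Segmentation-stage failure."""


class DegenerateHistogramError(SegmentationError):
    """ROI intensities carry no structure (constant / single bin)."""


class RegistrationError(CanalvolError):
    """Alignment failure (non-overlapping volumes, singular transform)."""


class VolumetryError(CanalvolError):
    """Defect quantification failure (grid mismatch, empty reference)."""
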