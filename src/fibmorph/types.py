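"""Core data containers shared across the pipeline.

Coordinate convention: arrays are indexed ``[row, col]`` with row = image y and
col = image x, pixel centers at integer coordinates, 0-based. All physical
lengths are in mm, derived from the pixel spacing carried by each grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, MetadataError

__all__ = [
    "SliceImage",
    "RoiMask",
    "SubjectStack",
    "CenterlineLoop",
    "SliceMorphometry",
    "SubjectMorphometry",
]


@dataclass
class SliceImage:
    """A single 2D intensity slice with physical pixel spacing.

    Parameters
    ----------
    values : ndarray
        2D array of dimensionless intensities.
    pixel_spacing : (float, float)
        In-plane spacing in mm, (row, col) order.
    slice_index : int
        Position of this slice in its stack (0-based).
    slice_thickness, slice_gap : float
        Through-plane geometry in mm; informational, not used in-plane.
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_index: int = 0
    slice_thickness: float = 4.0
    slice_gap: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise MetadataError("slice image must be a non-empty 2D grid")
        if self.pixel_spacing is None:
            raise MetadataError("pixel spacing is required (no silent default)")
        sy, sx = float(self.pixel_spacing[0]), float(self.pixel_spacing[1])
        if not (sy > 0 and sx > 0):
            raise MetadataError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        self.pixel_spacing = (sy, sx)
        if not np.all(np.isfinite(self.values)):
            raise MetadataError("slice image contains non-finite intensities")


@dataclass
class RoiMask:
    """A binary region-of-interest mask aligned to a :class:`SliceImage`."""

    values: np.ndarray
    pixel_spacing: tuple[float, float]
    label: str = "bone"
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values) > 0
        if self.values.ndim != 2 or self.values.size == 0:
            raise MetadataError("mask must be a non-empty 2D grid")
        if self.pixel_spacing is None:
            raise MetadataError("pixel spacing is required (no silent default)")
        sy, sx = float(self.pixel_spacing[0]), float(self.pixel_spacing[1])
        if not (sy > 0 and sx > 0):
            raise MetadataError(f"pixel spacing must be positive, got {self.pixel_spacing}")
        self.pixel_spacing = (sy, sx)
        if self.label not in ("bone", "marrow"):
            raise MetadataError(f"mask label must be 'bone' or 'marrow', got {self.label!r}")

    def check_aligned(self, image: SliceImage) -> None:
        if self.values.shape != image.values.shape:
            raise AlignmentError(
                f"mask shape {self.values.shape} != image shape {image.values.shape}"
            )
        if not np.allclose(self.pixel_spacing, image.pixel_spacing):
            raise AlignmentError(
                f"mask spacing {self.pixel_spacing} != image spacing {image.pixel_spacing}"
            )

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


@dataclass
class SubjectStack:
    """Ordered multi-slice data for one subject, with covariates.

    ``slices`` is a list of ``(SliceImage, bone RoiMask, marrow RoiMask)``
    tuples with strictly increasing slice indices.
    """

    subject_id: str
    slices: list[tuple[SliceImage, RoiMask, RoiMask]]
    age: float | None = None
    sex: str | None = None
    bmi: float | None = None
    mfi_class: str | None = None
    sft: float | None = None

    def __post_init__(self) -> None:
        idx = [img.slice_index for img, _, _ in self.slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise MetadataError("slice indices must be strictly increasing")
        for img, bone, marrow in self.slices:
            bone.check_aligned(img)
            marrow.check_aligned(img)

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class CenterlineLoop:
    """Ordered pixel path through the bone wall's medial axis.

    ``pixel_path`` lists (row, col) coordinates; consecutive entries are
    8-neighbors and no pixel repeats. For a closed loop the path wraps from
    the last pixel back to the first (the closing step is implicit, not a
    duplicated pixel).
    """

    pixel_path: list[tuple[int, int]]
    is_closed: bool
    length_mm: float = float("nan")

    def __len__(self) -> int:
        return len(self.pixel_path)


@dataclass
class SliceMorphometry:
    """Per-slice morphometric quantities (lengths in mm, areas in mm²)."""

    BA: float
    CL: float
    BT: float
    centerline_diameter: float
    D_out: float
    D_in: float
    g: float
    MPI: float
    BMA: float
    is_closed: bool
    slice_index: int = 0
    flags: list[str] = field(default_factory=list)


@dataclass
class SubjectMorphometry:
    """Per-subject morphometry averaged over the central slices."""

    subject_id: str
    BT: float
    BA: float
    CL: float
    g: float
    MPI: float
    BMA: float
    n_slices_used: int
    per_slice: list[SliceMorphometry]
    flags: list[str] = field(default_factory=list)
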