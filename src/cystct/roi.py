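"""Lesion ROI handling: masked-outline images, bounding boxes, patches.

Two preprocessing arms start here.  The *manual* arm keeps the radiologist's
outline literally: everything outside the mask is blanked to a fill value.
The *semi-automatic* arm finds the tight bounding box of the outline,
expands it 2 pixels outward, and crops the rectangle — lesion plus a thin
rim of surrounding tissue.

Coordinate convention (used package-wide): 0-based row/column indices,
boxes inclusive on both ends, so a box spanning rows 10..20 has height 11
and "expand by 2" literally moves each side 2 pixels outward.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .multichannel import DEFAULT_WINDOW

__all__ = [
    "CTSlice",
    "BoundingBox",
    "EmptyMaskError",
    "ShapeMismatchError",
    "BoxOutOfBoundsError",
    "masked_roi_image",
    "tight_bounding_box",
    "expand_box",
    "extract_patch",
    "load_dicom_slice",
]


class EmptyMaskError(ValueError):
    """Raised when an ROI mask contains no lesion pixels."""


class ShapeMismatchError(ValueError):
    """Raised when an image and its mask disagree in shape."""


class BoxOutOfBoundsError(ValueError):
    """Raised when a bounding box does not fit inside the image."""


@dataclass
class CTSlice:
    """One grayscale CT slice in HU scale with an optional lesion mask."""

    image: np.ndarray
    mask: np.ndarray | None = None
    label: str | None = None
    patient_id: str | None = None
    slice_index: int = 0


@dataclass(frozen=True)
class BoundingBox:
    """Rectangular pixel region, inclusive on both ends, 0-based."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError(f"degenerate box {self}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min + 1, self.col_max - self.col_min + 1)

    def fits(self, image_shape: tuple[int, int]) -> bool:
        return (
            self.row_min >= 0
            and self.col_min >= 0
            and self.row_max < image_shape[0]
            and self.col_max < image_shape[1]
        )


def masked_roi_image(
    image: np.ndarray, mask: np.ndarray, fill: float | None = None
) -> np.ndarray:
    """Blank everything outside the outlined lesion.

    ``fill`` defaults to the lower bound of the default soft-tissue display
    window, rendering the surroundings as the darkest displayable tissue.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ShapeMismatchError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    if not mask.any():
        raise EmptyMaskError("ROI mask is empty")
    if fill is None:
        fill = DEFAULT_WINDOW.lower
    out = np.full_like(image, float(fill))
    out[mask] = image[mask]
    return out


def tight_bounding_box(mask: np.ndarray) -> BoundingBox:
    """Smallest box containing every mask pixel."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("ROI mask is empty")
    return BoundingBox(
        int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())
    )


def expand_box(
    box: BoundingBox, margin: int = 2, image_shape: tuple[int, int] | None = None
) -> BoundingBox:
    """Move every side of ``box`` outward by ``margin`` pixels, clipping to the image."""
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if image_shape is not None and not box.fits(image_shape):
        raise BoxOutOfBoundsError(f"{box} exceeds image of shape {image_shape}")
    r0, c0 = box.row_min - margin, box.col_min - margin
    r1, c1 = box.row_max + margin, box.col_max + margin
    if image_shape is not None:
        r0, c0 = max(r0, 0), max(c0, 0)
        r1 = min(r1, image_shape[0] - 1)
        c1 = min(c1, image_shape[1] - 1)
    return BoundingBox(r0, c0, r1, c1)


def extract_patch(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Copy the rectangular sub-image; HU values are preserved, never rescaled."""
    image = np.asarray(image)
    if not box.fits(image.shape):
        raise BoxOutOfBoundsError(f"{box} exceeds image of shape {image.shape}")
    return image[box.row_min : box.row_max + 1, box.col_min : box.col_max + 1].copy()


def load_dicom_slice(path: str | Path) -> np.ndarray:
    """Read one DICOM slice and return pixel data in HU (slope/intercept applied)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept
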