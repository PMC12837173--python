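"""Shared domain types and error hierarchy.

Coordinate convention, used everywhere in this package: image origin is the
top-left corner, x runs right (columns), y runs down (rows), and the pixel at
array index ``(i, j)`` has its *center* at continuous coordinates
``(x, y) = (j + 0.5, i + 0.5)`` in pixel units.  Physical calibration is a
single isotropic scale ``mm_per_px = field_mm / width_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

CenterType = Literal["macula", "onh"]
Laterality = Literal["OD", "OS"]


class OctaError(Exception):
    """Base class for pipeline-specific failures."""


class UndersaturatedError(OctaError):
    """Requested vessel density is unreachable with the configured seed count."""


class EmptyRegionError(OctaError):
    """A density was requested over a region mask with no pixels."""


class GridClippedError(OctaError):
    """The ETDRS grid extends outside the image by more than the tolerated sliver."""

    def __init__(self, clipped_fraction: float):
        self.clipped_fraction = clipped_fraction
        super().__init__(f"grid-clipped: {clipped_fraction:.4f} of the grid falls outside the image")


class InvalidOutlineError(OctaError):
    """FAZ outline is not a simple closed polygon with >= 3 vertices."""


class NoFazAtCenterError(OctaError):
    """The grid-center pixel lies on a vessel, so no avascular zone can be grown."""


class UnboundedFazError(OctaError):
    """The avascular flood fill reached the image border; no FAZ can be determined."""


@dataclass(frozen=True)
class ImageSpec:
    """Geometry and physical calibration of a square en-face angiogram.

    Parameters
    ----------
    width_px, height_px
        Image dimensions; scans are square so these must be equal.
    field_mm
        Physical side length of the scan field (3.0 mm for macula scans,
        6.0 mm for optic-nerve-head scans).
    center_type
        Whether the scan is centered on the macula or the optic nerve head.
    laterality
        Which eye: ``"OD"`` (right) or ``"OS"`` (left).  Controls the
        nasal/temporal quadrant assignment.
    """

    width_px: int
    height_px: int
    field_mm: float
    center_type: CenterType
    laterality: Laterality = "OD"

    def __post_init__(self) -> None:
        if self.width_px != self.height_px:
            raise ValueError("en-face scans are square: width_px must equal height_px")
        if self.width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not (self.field_mm > 0 and np.isfinite(self.field_mm)):
            raise ValueError("field_mm must be finite and positive")
        if self.center_type not in ("macula", "onh"):
            raise ValueError(f"unknown center_type {self.center_type!r}")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"unknown laterality {self.laterality!r}")

    @property
    def mm_per_px(self) -> float:
        return self.field_mm / self.width_px

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)

    def pixel_centers_mm(self, center_px: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
        """Return (dx, dy) arrays in mm from ``center_px`` to every pixel center."""
        cx, cy = center_px
        ys, xs = np.mgrid[0 : self.height_px, 0 : self.width_px]
        dx = (xs + 0.5 - cx) * self.mm_per_px
        dy = (ys + 0.5 - cy) * self.mm_per_px
        return dx, dy


MACULA_SPEC = ImageSpec(512, 512, 3.0, "macula")
ONH_SPEC = ImageSpec(512, 512, 6.0, "onh")


def as_float01(img: np.ndarray) -> np.ndarray:
    """Normalize an image to float on the [0, 1] intensity scale.

    8-bit input is divided by 255; float input is passed through unchanged
    (callers are responsible for supplying floats already on a [0, 1]-like
    scale — no min/max rescaling is applied, so constant offsets survive).
    """
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float64) / 65535.0
    return np.asarray(img, dtype=np.float64)
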