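"""In-memory image containers and regions of interest.

Conventions: image origin top-left, row-major, x = column index; pixel
coordinates are 0-based; physical coordinates are in μm with circle ROIs
given as (cx, cy, radius).  A pixel's physical position is the position of
its center, ``(ix + 0.5) * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SPRImage", "CircleROI"]

_UNITS = ("reflectance", "delta_R", "ratio", "counts", "arbitrary")


@dataclass
class SPRImage:
    """2-D reflectivity (or ΔR) map with imaging metadata."""

    pixels: np.ndarray
    pixel_size_um: float
    wavelength_nm: float = float("nan")
    polarization: str = "p"  # p | s | ratio
    units: str = "reflectance"
    mask: np.ndarray | None = None  # True where invalid (e.g. s-floor pixels)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.units not in _UNITS:
            raise ValueError(f"units must be one of {_UNITS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in μm."""
        return (
            self.shape[1] * self.pixel_size_um,
            self.shape[0] * self.pixel_size_um,
        )

    def pixel_centers_um(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate grids of pixel centers in μm."""
        y, x = np.mgrid[0 : self.shape[0], 0 : self.shape[1]]
        return (x + 0.5) * self.pixel_size_um, (y + 0.5) * self.pixel_size_um

    def with_pixels(self, pixels: np.ndarray, units: str | None = None) -> "SPRImage":
        return SPRImage(
            pixels,
            self.pixel_size_um,
            self.wavelength_nm,
            self.polarization,
            units or self.units,
            self.mask,
        )


@dataclass(frozen=True)
class CircleROI:
    """Circular region of interest in physical μm coordinates."""

    cx_um: float
    cy_um: float
    radius_um: float

    def __post_init__(self):
        if not self.radius_um > 0:
            raise ValueError("ROI radius must be > 0")

    def dilated(self, extra_radius_um: float) -> "CircleROI":
        return CircleROI(self.cx_um, self.cy_um, self.radius_um + extra_radius_um)

    def mask(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        """Boolean mask, pixel-center inclusion rule."""
        y, x = np.mgrid[0 : shape[0], 0 : shape[1]]
        xc = (x + 0.5) * pixel_size_um
        yc = (y + 0.5) * pixel_size_um
        return (xc - self.cx_um) ** 2 + (yc - self.cy_um) ** 2 <= self.radius_um**2
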