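"""Convenience constructors for the sensor stacks used throughout.

The instrument couples light through a high-index coverslip (n = 1.78,
matched to the 1.65 NA objective) carrying a ~45 nm sputtered gold film,
with water (or buffer) as the sensing medium.  The thin chromium adhesion
layer is ignored, consistent with the 3-layer glass/gold/media model the
angle scans are fit with.
"""

from __future__ import annotations

from .dispersion import GOLD, WATER, DispersionTable
from .optics import OpticalLayer, OpticalStack

__all__ = ["gold_sensor_stack", "bead_gap_stack"]

N_COVERSLIP = 1.78
GOLD_THICKNESS_NM = 45.0


def gold_sensor_stack(
    wavelength_nm: float,
    gold_thickness_nm: float = GOLD_THICKNESS_NM,
    n_glass: float = N_COVERSLIP,
    gold: DispersionTable = GOLD,
    water: DispersionTable = WATER,
) -> OpticalStack:
    """3-layer glass / gold / water sensor stack at one wavelength."""
    return OpticalStack(
        [
            OpticalLayer("glass", n_glass**2),
            OpticalLayer("gold", gold, gold_thickness_nm),
            OpticalLayer("water", water),
        ],
        wavelength_nm,
    )


def bead_gap_stack(
    wavelength_nm: float,
    bead_index: float,
    gap_nm: float = 0.0,
    gold_thickness_nm: float = GOLD_THICKNESS_NM,
    n_glass: float = N_COVERSLIP,
    gold: DispersionTable = GOLD,
    water: DispersionTable = WATER,
) -> OpticalStack:
    """4-layer glass / gold / water-gap / bead stack (ray-local bead model).

    The locally curved bead surface above each pixel is treated as a flat
    semi-infinite slab of the bead material separated from the gold by a
    water gap of thickness ``gap_nm``.
    """
    return OpticalStack(
        [
            OpticalLayer("glass", n_glass**2),
            OpticalLayer("gold", gold, gold_thickness_nm),
            OpticalLayer("water_gap", water, gap_nm),
            OpticalLayer("bead", bead_index**2),
        ],
        wavelength_nm,
    )
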