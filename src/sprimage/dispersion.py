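"""Wavelength-dependent optical constants.

A :class:`DispersionTable` holds a small tabulation of complex refractive
index ``n + ik`` versus vacuum wavelength and interpolates linearly in ``n``
and ``k`` separately (not in the permittivity).  Two built-in tables cover
the visible range used by the instrument model:

``GOLD``
    A smoothed, rounded visible-range compilation for sputtered gold films
    of the handbook type (ε ≈ −12.2 + 1.7i at 620 nm).  Published gold
    tabulations disagree noticeably in the red — coupling angles shift by
    ~1–2° and penetration depths by ~10–20% between them — so the table is
    swappable everywhere a stack is built (see the config reference).

``WATER``
    Pure water at room temperature; absorption is negligible at these
    thicknesses and is tabulated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DispersionTable", "dielectric_lookup", "GOLD", "WATER", "BUILTIN_TABLES"]


@dataclass(frozen=True)
class DispersionTable:
    """Tabulated complex refractive index n(λ) + i·k(λ).

    Wavelengths must be strictly increasing and at least two entries are
    required; queries outside the tabulated range raise ``ValueError``
    rather than extrapolating.
    """

    wavelength_nm: np.ndarray
    n: np.ndarray
    k: np.ndarray
    name: str = "unnamed"

    def __post_init__(self):
        object.__setattr__(self, "wavelength_nm", np.asarray(self.wavelength_nm, float))
        object.__setattr__(self, "n", np.asarray(self.n, float))
        object.__setattr__(self, "k", np.asarray(self.k, float))
        wl = self.wavelength_nm
        if wl.size < 2:
            raise ValueError("dispersion table needs at least 2 entries")
        if not (np.diff(wl) > 0).all():
            raise ValueError("dispersion table wavelengths must be strictly increasing")
        if wl.size != self.n.size or wl.size != self.k.size:
            raise ValueError("wavelength, n and k columns must have equal length")
        if (self.k < 0).any():
            raise ValueError("extinction coefficient k must be >= 0")

    def _check_range(self, wavelength_nm: float) -> None:
        lo, hi = self.wavelength_nm[0], self.wavelength_nm[-1]
        if not (lo <= wavelength_nm <= hi):
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside tabulated range "
                f"[{lo}, {hi}] nm of table '{self.name}'"
            )

    def index_at(self, wavelength_nm: float) -> complex:
        """Complex refractive index n + ik, linearly interpolated."""
        self._check_range(wavelength_nm)
        n = float(np.interp(wavelength_nm, self.wavelength_nm, self.n))
        k = float(np.interp(wavelength_nm, self.wavelength_nm, self.k))
        return complex(n, k)

    def epsilon_at(self, wavelength_nm: float) -> complex:
        """Complex relative permittivity ε = (n + ik)²."""
        nk = self.index_at(wavelength_nm)
        return nk * nk


def dielectric_lookup(table: DispersionTable, wavelength_nm: float) -> complex:
    """Permittivity ε = (n + ik)² at ``wavelength_nm`` from ``table``.

    n and k are interpolated linearly in wavelength, each on its own
    (interpolating ε directly would mix them nonlinearly).
    """
    return table.epsilon_at(wavelength_nm)


GOLD = DispersionTable(
    wavelength_nm=[450.0, 480.0, 515.0, 550.0, 590.0, 620.0, 670.0, 700.0, 750.0],
    n=[1.40, 1.00, 0.62, 0.43, 0.30, 0.24, 0.19, 0.17, 0.16],
    k=[1.88, 1.97, 2.30, 2.72, 3.18, 3.50, 3.96, 4.24, 4.68],
    name="gold (visible-range film compilation)",
)

WATER = DispersionTable(
    wavelength_nm=[450.0, 480.0, 515.0, 550.0, 590.0, 620.0, 670.0, 700.0, 750.0],
    n=[1.3390, 1.3374, 1.3357, 1.3344, 1.3330, 1.3323, 1.3309, 1.3305, 1.3298],
    k=np.zeros(9),
    name="water",
)

BUILTIN_TABLES = {"gold": GOLD, "water": WATER}
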