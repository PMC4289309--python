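"""Independent reference implementations used only by the tests.

The Parratt downward recursion is the classical alternative to the
characteristic-matrix solution for stratified media; it shares no code with
the package and serves as the independent oracle for reflectance values.
"""

from __future__ import annotations

import numpy as np


def _kz(eps, k0, kx):
    kz = np.sqrt(eps * k0 * k0 - kx * kx + 0j)
    return -kz if np.imag(kz) < 0 else kz


def parratt_reflection(eps, d, wavelength_nm, angle_deg, polarization):
    """Amplitude reflection coefficient by the Parratt recursion.

    ``eps``: permittivities top→bottom; ``d``: thicknesses (None at the
    semi-infinite ends).  exp(-iωt) convention, Im(kz) >= 0.
    """
    k0 = 2 * np.pi / wavelength_nm
    n0 = np.sqrt(eps[0]).real
    kx = k0 * n0 * np.sin(np.radians(angle_deg))
    kz = [_kz(e, k0, kx) for e in eps]

    def fresnel(i, j):
        if polarization == "p":
            return (eps[j] * kz[i] - eps[i] * kz[j]) / (
                eps[j] * kz[i] + eps[i] * kz[j]
            )
        return (kz[i] - kz[j]) / (kz[i] + kz[j])

    r = fresnel(len(eps) - 2, len(eps) - 1)
    for i in range(len(eps) - 3, -1, -1):
        phase = np.exp(2j * kz[i + 1] * d[i + 1])
        rij = fresnel(i, i + 1)
        r = (rij + r * phase) / (1 + rij * r * phase)
    return r


def parratt_reflectance(eps, d, wavelength_nm, angle_deg, polarization="p"):
    return float(np.abs(parratt_reflection(eps, d, wavelength_nm, angle_deg, polarization)) ** 2)
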