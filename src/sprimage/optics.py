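"""Thin-film optics for objective-launched surface plasmon resonance.

The physical model is the classic stratified-medium (Abelès characteristic
matrix) solution for plane-wave reflection from a stack of isotropic layers
with complex permittivities.  A glass/gold/water stack illuminated with
p-polarized light beyond the critical angle shows the SPR reflectance
minimum; the same machinery evaluates the 4-layer glass/gold/water-gap/bead
model used by the synthetic-scene generator.

Conventions
-----------
* time dependence ``exp(-iωt)``; absorbing media have ``Im(ε) ≥ 0``;
* transverse wavevectors take the ``Im(kz) ≥ 0`` branch so fields decay
  away from the interface;
* angles in degrees, wavelengths and layer thicknesses in nm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .dispersion import DispersionTable, dielectric_lookup

__all__ = [
    "OpticalLayer",
    "OpticalStack",
    "AngleScan",
    "EvanescentProfile",
    "stack_reflectance",
    "stack_transmittance",
    "spr_angle_scan",
    "spr_minimum_angle",
    "critical_angle",
    "angle_at_reflectance",
    "penetration_depth",
    "field_decay",
    "propagation_length",
    "diffraction_limit",
]

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class OpticalLayer:
    """One layer of a stratified stack.

    ``permittivity`` is either a complex ε valid at the stack wavelength or
    a :class:`DispersionTable` resolved when the stack is evaluated.
    ``thickness_nm`` is ``None`` for the semi-infinite first/last layers.
    """

    name: str
    permittivity: complex | DispersionTable
    thickness_nm: float | None = None

    def __post_init__(self):
        if self.thickness_nm is not None and self.thickness_nm < 0:
            raise ValueError(f"layer '{self.name}': thickness must be >= 0")
        if isinstance(self.permittivity, (int, float, complex)):
            if complex(self.permittivity).imag < 0:
                raise ValueError(
                    f"layer '{self.name}': Im(eps) must be >= 0 (absorbing convention)"
                )

    def epsilon(self, wavelength_nm: float) -> complex:
        if isinstance(self.permittivity, DispersionTable):
            return dielectric_lookup(self.permittivity, wavelength_nm)
        return complex(self.permittivity)


@dataclass(frozen=True)
class OpticalStack:
    """Ordered layers (light enters through ``layers[0]``) at one wavelength."""

    layers: tuple[OpticalLayer, ...]
    wavelength_nm: float

    def __init__(self, layers: Sequence[OpticalLayer], wavelength_nm: float):
        layers = tuple(layers)
        if len(layers) < 2:
            raise ValueError("a stack needs at least 2 layers")
        if layers[0].thickness_nm is not None or layers[-1].thickness_nm is not None:
            raise ValueError("first and last layers are semi-infinite (thickness None)")
        eps0 = layers[0].epsilon(wavelength_nm)
        if abs(eps0.imag) > 1e-12 or eps0.real <= 0:
            raise ValueError("incidence medium must be transparent (real positive eps)")
        for lay in layers[1:-1]:
            if lay.thickness_nm is None:
                raise ValueError(f"interior layer '{lay.name}' needs a thickness")
        object.__setattr__(self, "layers", layers)
        object.__setattr__(self, "wavelength_nm", float(wavelength_nm))

    def epsilons(self) -> list[complex]:
        return [lay.epsilon(self.wavelength_nm) for lay in self.layers]

    def thicknesses(self) -> list[float | None]:
        return [lay.thickness_nm for lay in self.layers]

    def n_incidence(self) -> float:
        return float(np.sqrt(self.layers[0].epsilon(self.wavelength_nm).real))

    def replace_thickness(self, index: int, thickness_nm: float) -> "OpticalStack":
        layers = list(self.layers)
        old = layers[index]
        layers[index] = OpticalLayer(old.name, old.permittivity, thickness_nm)
        return OpticalStack(layers, self.wavelength_nm)


@dataclass
class AngleScan:
    """Reflectance versus incident angle at one wavelength/polarization."""

    angles_deg: np.ndarray
    reflectance: np.ndarray
    polarization: str = "p"
    wavelength_nm: float = float("nan")

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, float)
        self.reflectance = np.asarray(self.reflectance, float)
        if self.angles_deg.size != self.reflectance.size:
            raise ValueError("angles and reflectance must have equal length")
        if self.angles_deg.size and (
            (self.angles_deg < 0).any() or (self.angles_deg >= 90).any()
        ):
            raise ValueError("angles must lie in [0, 90) degrees")
        if self.polarization not in ("p", "s"):
            raise ValueError("polarization must be 'p' or 's'")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"angle_deg": self.angles_deg, "reflectance": self.reflectance}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, polarization="p", wavelength_nm=float("nan")) -> "AngleScan":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(
            df["angle_deg"].to_numpy(),
            df["reflectance"].to_numpy(),
            polarization,
            wavelength_nm,
        )


@dataclass(frozen=True)
class EvanescentProfile:
    """Exponential evanescent-intensity profile I(z) = I0·exp(−z/Lp)."""

    penetration_depth_nm: float
    intensity0: float = 1.0

    def __post_init__(self):
        if not self.penetration_depth_nm > 0:
            raise ValueError("penetration depth must be > 0")


# ---------------------------------------------------------------------------
# transfer-matrix core


def _kz(eps, k0, kx):
    """Transverse wavevector with the Im >= 0 decay branch."""
    kz = np.sqrt(eps * k0 * k0 - kx * kx + 0j)
    return np.where(kz.imag < 0, -kz, kz)


def _amplitude_coefficients(eps, d, wavelength_nm, angle_deg, polarization):
    """Amplitude reflection/transmission of a stratified stack.

    ``eps``: complex permittivity per layer; ``d``: thicknesses in nm (None
    for the semi-infinite ends; interior entries may be numpy arrays, which
    broadcast — used for per-pixel gap sweeps).  Returns (r, t, eta0, etaN)
    in the admittance normalization where the transmitted power fraction is
    ``Re(etaN)/eta0 * |t|**2``.
    """
    if polarization not in ("p", "s"):
        raise ValueError("polarization must be 'p' or 's'")
    angle = np.asarray(angle_deg, float)
    if np.any(angle < 0) or np.any(angle >= 90):
        raise ValueError("incident angle must lie in [0, 90) degrees")
    k0 = 2 * np.pi / wavelength_nm
    n0 = np.sqrt(eps[0].real)
    kx = k0 * n0 * np.sin(angle * _DEG)

    def eta(eps_j, kz_j):
        # optical admittance (up to a constant factor that cancels in r/t)
        return eps_j / kz_j if polarization == "p" else kz_j + 0j

    kz0 = _kz(eps[0], k0, kx)
    kzN = _kz(eps[-1], k0, kx)
    eta0 = eta(eps[0], kz0)
    etaN = eta(eps[-1], kzN)

    # characteristic matrix product over interior layers
    m11 = np.ones_like(kx, dtype=complex)
    m12 = np.zeros_like(m11)
    m21 = np.zeros_like(m11)
    m22 = np.ones_like(m11)
    for eps_j, d_j in zip(eps[1:-1], d[1:-1]):
        kz_j = _kz(eps_j, k0, kx)
        eta_j = eta(eps_j, kz_j)
        delta = kz_j * np.asarray(d_j)
        # exp(-iωt) convention: forward wave exp(+i kz z), hence the minus
        # signs relative to the exp(+iωt) form of the characteristic matrix
        c, s = np.cos(delta), np.sin(delta)
        a11, a12 = c, -1j * s / eta_j
        a21, a22 = -1j * eta_j * s, c
        m11, m12, m21, m22 = (
            m11 * a11 + m12 * a21,
            m11 * a12 + m12 * a22,
            m21 * a11 + m22 * a21,
            m21 * a12 + m22 * a22,
        )

    b = m11 + m12 * etaN
    c = m21 + m22 * etaN
    r = (eta0 * b - c) / (eta0 * b + c)
    t = 2 * eta0 / (eta0 * b + c)
    return r, t, eta0, etaN


def stack_reflectance(stack: OpticalStack, angle_deg, polarization: str = "p"):
    """Power reflectance |r|² of the stack at the given incidence angle(s).

    Scalar in, scalar out; array of angles in, array out.  p and s coincide
    at normal incidence.
    """
    r, *_ = _amplitude_coefficients(
        stack.epsilons(), stack.thicknesses(), stack.wavelength_nm, angle_deg, polarization
    )
    R = np.abs(r) ** 2
    return float(R) if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0 else R


def stack_transmittance(stack: OpticalStack, angle_deg, polarization: str = "p"):
    """Transmitted power fraction into the final semi-infinite medium."""
    r, t, eta0, etaN = _amplitude_coefficients(
        stack.epsilons(), stack.thicknesses(), stack.wavelength_nm, angle_deg, polarization
    )
    T = etaN.real / eta0.real * np.abs(t) ** 2
    return float(T) if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0 else T


def gap_reflectance(
    stack: OpticalStack,
    gap_layer_index: int,
    gap_nm,
    angle_deg: float,
    polarization: str = "p",
):
    """Reflectance with one interior layer's thickness swept over an array.

    Used by the scene generator to evaluate the 4-layer
    glass/gold/water-gap/bead model as a function of the water-gap
    thickness under each pixel in a single vectorized call.
    """
    d = stack.thicknesses()
    if not 0 < gap_layer_index < len(d) - 1:
        raise ValueError("gap layer must be an interior layer")
    d[gap_layer_index] = np.asarray(gap_nm, float)
    r, *_ = _amplitude_coefficients(
        stack.epsilons(), d, stack.wavelength_nm, angle_deg, polarization
    )
    return np.abs(r) ** 2


def spr_angle_scan(stack: OpticalStack, angles_deg, polarization: str = "p") -> AngleScan:
    """Element-wise reflectance scan preserving the input angle order."""
    angles = np.atleast_1d(np.asarray(angles_deg, float))
    if angles.size == 0:
        raise ValueError("angle list must be nonempty")
    R = stack_reflectance(stack, angles, polarization)
    return AngleScan(angles, np.atleast_1d(R), polarization, stack.wavelength_nm)


def critical_angle(stack: OpticalStack) -> float | None:
    """Critical angle (degrees) w.r.t. the final medium, None if none exists."""
    n_last = np.sqrt(stack.layers[-1].epsilon(stack.wavelength_nm)).real
    n0 = stack.n_incidence()
    if n_last >= n0:
        return None
    return float(np.degrees(np.arcsin(n_last / n0)))


def spr_minimum_angle(
    stack: OpticalStack,
    polarization: str = "p",
    coarse_step_deg: float = 0.05,
    tol_deg: float = 1e-3,
) -> float | None:
    """Angle of the global reflectance minimum beyond the critical angle.

    Coarse grid search followed by bounded local refinement (well below the
    0.01° requirement).  Returns ``None`` when no sub-unity minimum exists
    beyond the critical angle (e.g. a lossless stack in total internal
    reflection) instead of raising.
    """
    theta_c = critical_angle(stack)
    lo = (theta_c + 10 * coarse_step_deg) if theta_c is not None else coarse_step_deg
    hi = 90.0 - coarse_step_deg
    if lo >= hi:
        return None
    grid = np.arange(lo, hi, coarse_step_deg)
    R = stack_reflectance(stack, grid, polarization)
    i = int(np.argmin(R))
    if R[i] > 0.999:  # flat unity shelf: no plasmon dip
        return None
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda th: stack_reflectance(stack, float(th), polarization),
        bounds=(a, b),
        method="bounded",
        options={"xatol": tol_deg},
    )
    return float(res.x)


def angle_at_reflectance(
    stack: OpticalStack,
    target_reflectance: float,
    polarization: str = "p",
    min_margin: float = 0.05,
) -> float:
    """Angle on the shallow (descending) flank where R equals ``target``.

    This is the instrument's operating point: slightly shallow of the SPR
    minimum, conventionally at R ≈ 0.1 so the response stays linear.  At
    short wavelengths the (lossier) gold dip does not reach 0.1; there the
    operating point falls back to R = R_min + ``min_margin``, i.e. still
    slightly shallow of the minimum with enough slope to respond.
    """
    theta_min = spr_minimum_angle(stack, polarization)
    if theta_min is None:
        raise ValueError("stack has no SPR minimum to sit shallow of")
    theta_c = critical_angle(stack)
    lo = theta_c + 0.2 if theta_c is not None else 0.2
    grid = np.linspace(lo, theta_min, 200)
    R = stack_reflectance(stack, grid, polarization)
    target_reflectance = max(target_reflectance, float(R.min()) + min_margin)
    if not R.max() > target_reflectance:
        raise ValueError(
            f"target reflectance {target_reflectance} not bracketed on the shallow flank"
        )
    j = int(np.nonzero(R >= target_reflectance)[0][-1])  # last angle still above target
    return float(
        brentq(
            lambda th: stack_reflectance(stack, float(th), polarization)
            - target_reflectance,
            grid[j],
            theta_min,
            xtol=1e-6,
        )
    )


# ---------------------------------------------------------------------------
# evanescent field theory


def penetration_depth(wavelength_nm: float, eps_metal: complex, eps_dielectric: float) -> float:
    """1/e intensity decay length Lp of the evanescent field, in nm.

    Lp = (λ/2π)·sqrt(|Re(ε_m) + ε_d|)/ε_d, the decay length of the
    evanescent intensity I(z) in the dielectric for a bound surface-plasmon
    mode.  Requires the bound-mode condition Re(ε_m) < −ε_d.
    """
    eps_m = complex(eps_metal).real
    eps_d = float(eps_dielectric)
    if not eps_m < -eps_d:
        raise ValueError(
            f"bound-mode condition Re(eps_metal) < -eps_dielectric violated "
            f"({eps_m} vs {-eps_d})"
        )
    return wavelength_nm / (2 * np.pi) * np.sqrt(abs(eps_m + eps_d)) / eps_d


def field_decay(z_nm, profile: EvanescentProfile):
    """Evanescent intensity I(z) = I0·exp(−z/Lp); z must be >= 0."""
    z = np.asarray(z_nm, float)
    if (z < 0).any():
        raise ValueError("z must be >= 0 (distance from the surface)")
    out = profile.intensity0 * np.exp(-z / profile.penetration_depth_nm)
    return float(out) if np.ndim(z_nm) == 0 else out


def surface_plasmon_wavevector(
    wavelength_nm: float, eps_metal: complex, eps_dielectric: float
) -> complex:
    """Complex k_sp = (2π/λ)·sqrt(ε_m ε_d/(ε_m + ε_d)), Im >= 0 branch, nm^-1."""
    eps_m = complex(eps_metal)
    eps_d = float(eps_dielectric)
    if not eps_m.real < -eps_d:
        raise ValueError("bound-mode condition Re(eps_metal) < -eps_dielectric violated")
    ksp = 2 * np.pi / wavelength_nm * np.sqrt(eps_m * eps_d / (eps_m + eps_d))
    if ksp.imag < 0:
        ksp = -ksp
    return ksp


def propagation_length(
    wavelength_nm: float, eps_metal: complex, eps_dielectric: float
) -> float:
    """Plasmon 1/e intensity propagation length along the surface, in μm.

    L_x = 1/(2·Im k_sp); returns ``inf`` for a lossless metal.
    """
    ksp = surface_plasmon_wavevector(wavelength_nm, eps_metal, eps_dielectric)
    if ksp.imag == 0:
        return float("inf")
    return 1.0 / (2.0 * ksp.imag) / 1000.0


def diffraction_limit(wavelength_nm: float, na: float) -> float:
    """Rayleigh resolution 0.61·λ/NA, in μm."""
    if not na > 0:
        raise ValueError("numerical aperture must be > 0")
    return 0.61 * wavelength_nm / na / 1000.0
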