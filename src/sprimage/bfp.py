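"""Back-focal-plane (BFP) geometry and angle-scan extraction.

In an objective-launched SPR microscope the radial position of light in the
objective's back focal plane encodes the incident angle at the sample: the
center of the BFP illuminates at 0° and the periphery at the maximum angle
the objective passes.  Patterning a thin crescent of light in the BFP
therefore selects a single incident angle (and a limited azimuthal range),
and a radial line scan of a fully illuminated BFP image *is* an SPR angle
scan.

The radius↔angle mapping used here is the Abbe sine condition normalized to
the stated periphery angle, ``r/R = sin(θ)/sin(θ_max)``.  ``θ_max`` defaults
to 60°, the instrument's calibrated periphery, and is deliberately decoupled
from NA/n (which would allow ≈68°): the calibration of the aperture edge is
an instrument property, not a theoretical one.

Azimuth convention: 0° along +x (the polarization axis, where the SPR dip
appears), increasing counter-clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares

from .optics import AngleScan, OpticalStack, stack_reflectance

__all__ = [
    "BFPGeometry",
    "CrescentSpec",
    "FresnelFitResult",
    "angle_to_bfp_radius",
    "bfp_radius_to_angle",
    "make_crescent_mask",
    "extract_angle_scan",
    "render_bfp_image",
    "fit_fresnel_scan",
]


@dataclass(frozen=True)
class BFPGeometry:
    """Geometry of the back-focal-plane aperture on the camera."""

    na: float = 1.65
    n_immersion: float = 1.78
    radius_px: float = 200.0
    center_px: tuple[float, float] = (200.0, 200.0)  # (x, y)
    max_angle_deg: float = 60.0

    def __post_init__(self):
        if self.na > self.n_immersion:
            raise ValueError("NA cannot exceed the immersion index")
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")
        if not 0 < self.max_angle_deg < 90:
            raise ValueError("max_angle_deg must lie in (0, 90)")


@dataclass(frozen=True)
class CrescentSpec:
    """Thin illumination arc in the BFP selecting one incident angle.

    ``center_angle_deg`` is the incident angle the arc selects,
    ``radial_width_deg`` its width in incident angle, ``azimuthal_span_deg``
    the arc length (the instrument uses ≈40°), ``azimuth_center_deg`` where
    the arc sits (0° = +x, the p-polarized axis).
    """

    center_angle_deg: float
    radial_width_deg: float = 2.0
    azimuthal_span_deg: float = 40.0
    azimuth_center_deg: float = 0.0

    def __post_init__(self):
        if self.radial_width_deg <= 0:
            raise ValueError("radial_width_deg must be > 0")
        if not 0 < self.azimuthal_span_deg <= 360:
            raise ValueError("azimuthal_span_deg must lie in (0, 360]")


def angle_to_bfp_radius(theta_deg, geom: BFPGeometry):
    """Normalized BFP radius r/R of the ray incident at ``theta_deg``."""
    theta = np.asarray(theta_deg, float)
    if (theta < 0).any() or (theta > geom.max_angle_deg).any():
        raise ValueError(f"theta must lie in [0, {geom.max_angle_deg}] degrees")
    out = np.sin(np.radians(theta)) / math.sin(math.radians(geom.max_angle_deg))
    return float(out) if np.ndim(theta_deg) == 0 else out


def bfp_radius_to_angle(r_norm, geom: BFPGeometry):
    """Inverse of :func:`angle_to_bfp_radius` (r/R in [0, 1] → degrees)."""
    r = np.asarray(r_norm, float)
    if (r < 0).any() or (r > 1).any():
        raise ValueError("normalized radius must lie in [0, 1]")
    out = np.degrees(np.arcsin(r * math.sin(math.radians(geom.max_angle_deg))))
    return float(out) if np.ndim(r_norm) == 0 else out


def _pixel_polar(shape, geom: BFPGeometry):
    cy, cx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = cx - geom.center_px[0]
    dy = cy - geom.center_px[1]
    r_norm = np.hypot(dx, dy) / geom.radius_px
    azimuth = np.degrees(np.arctan2(dy, dx))  # (-180, 180], 0 along +x
    return r_norm, azimuth


def make_crescent_mask(
    spec: CrescentSpec, geom: BFPGeometry, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Boolean mask of the crescent illumination pattern.

    Radial inclusion is by pixel center; at the azimuthal ends a pixel is
    included only when the arc covers at least half of the pixel's own
    angular footprint, so a vanishing span yields an empty mask.
    """
    lo = spec.center_angle_deg - spec.radial_width_deg / 2
    hi = spec.center_angle_deg + spec.radial_width_deg / 2
    if lo < 0 or hi > geom.max_angle_deg:
        raise ValueError(
            f"radial band [{lo}, {hi}]° falls outside the aperture "
            f"[0, {geom.max_angle_deg}]°"
        )
    if shape is None:
        n = int(math.ceil(2 * geom.radius_px)) + 1
        shape = (n, n)
    r_norm, azimuth = _pixel_polar(shape, geom)
    r_lo = angle_to_bfp_radius(lo, geom)
    r_hi = angle_to_bfp_radius(hi, geom)
    d_az = np.abs((azimuth - spec.azimuth_center_deg + 180.0) % 360.0 - 180.0)
    half = spec.azimuthal_span_deg / 2
    # angular footprint of one pixel at its radius
    w = np.degrees(1.0 / np.maximum(r_norm * geom.radius_px, 1e-9))
    overlap = np.minimum(half, d_az + w / 2) - np.maximum(-half, d_az - w / 2)
    return (r_norm >= r_lo) & (r_norm <= r_hi) & (overlap >= w / 2)


def render_bfp_image(
    reflectance_of_angle,
    geom: BFPGeometry,
    shape: tuple[int, int] | None = None,
    polarization_weighting: bool = False,
    outside_value: float = 0.0,
) -> np.ndarray:
    """Render a synthetic BFP image from a reflectance curve R(θ).

    With ``polarization_weighting`` the pixel value interpolates between the
    p response along ±x and the s response along ±y as cos²/sin² of the
    azimuth, mimicking a linearly x-polarized illumination; in that case
    ``reflectance_of_angle`` must accept ``(theta_deg, polarization)``.
    """
    if shape is None:
        n = int(math.ceil(2 * geom.radius_px)) + 1
        shape = (n, n)
    r_norm, azimuth = _pixel_polar(shape, geom)
    inside = r_norm <= 1.0
    theta = np.zeros(shape)
    theta[inside] = bfp_radius_to_angle(r_norm[inside], geom)
    img = np.full(shape, outside_value, float)
    if polarization_weighting:
        rp = reflectance_of_angle(theta[inside], "p")
        rs = reflectance_of_angle(theta[inside], "s")
        c2 = np.cos(np.radians(azimuth[inside])) ** 2
        img[inside] = c2 * rp + (1 - c2) * rs
    else:
        img[inside] = reflectance_of_angle(theta[inside])
    return img


def extract_angle_scan(
    bfp_image: np.ndarray,
    geom: BFPGeometry,
    azimuth_deg: float = 0.0,
    n_samples: int | None = None,
    wavelength_nm: float = float("nan"),
    polarization: str = "p",
) -> AngleScan:
    """Radial line scan of a BFP image converted to an angle scan.

    Samples the image by bilinear interpolation along the ray at
    ``azimuth_deg`` from the aperture center to the periphery and converts
    each radial position to an incident angle by inverting the sine
    mapping.  The ray must stay inside the image.
    """
    if n_samples is None:
        n_samples = max(int(geom.radius_px), 16)
    r = np.linspace(0.0, 1.0, n_samples)
    ax = math.cos(math.radians(azimuth_deg))
    ay = math.sin(math.radians(azimuth_deg))
    x = geom.center_px[0] + r * geom.radius_px * ax
    y = geom.center_px[1] + r * geom.radius_px * ay
    if (
        x.min() < 0
        or y.min() < 0
        or x.max() > bfp_image.shape[1] - 1
        or y.max() > bfp_image.shape[0] - 1
    ):
        raise ValueError("scan ray leaves the image bounds")
    vals = map_coordinates(np.asarray(bfp_image, float), [y, x], order=1)
    angles = bfp_radius_to_angle(r, geom)
    return AngleScan(angles, vals, polarization, wavelength_nm)


@dataclass
class FresnelFitResult:
    """Outcome of fitting a measured angle scan with the Fresnel model."""

    stack: OpticalStack
    gold_thickness_nm: float
    intensity_scale: float
    angle_offset_deg: float
    residual_rms: float
    success: bool
    message: str = ""

    def normalize(self, scan: AngleScan) -> AngleScan:
        """Convert a camera-unit scan to reflectivity units using the fit."""
        return AngleScan(
            scan.angles_deg + self.angle_offset_deg,
            scan.reflectance / self.intensity_scale,
            scan.polarization,
            scan.wavelength_nm,
        )


def fit_fresnel_scan(
    scan: AngleScan,
    stack_template: OpticalStack,
    gold_layer_index: int = 1,
    max_angle_offset_deg: float = 2.0,
) -> FresnelFitResult:
    """Least-squares fit of the multilayer Fresnel model to an angle scan.

    Free parameters: the gold film thickness, a multiplicative intensity
    scale (camera counts per reflectivity unit) and a small angle offset.
    The intensity scale is what converts raw BFP line-scan counts into
    reflectivity units; fitting it makes the procedure invariant to overall
    rescaling of the input.  Non-convergence is flagged on the result, not
    raised.
    """
    angles = scan.angles_deg
    values = scan.reflectance
    d0 = stack_template.layers[gold_layer_index].thickness_nm

    def model(thickness, offset):
        st = stack_template.replace_thickness(gold_layer_index, thickness)
        th = np.clip(angles + offset, 0.0, 89.999)
        return stack_reflectance(st, th, scan.polarization)

    m0 = model(d0, 0.0)
    scale0 = float(np.dot(values, m0) / np.dot(m0, m0))

    def residuals(params):
        thickness, scale, offset = params
        return scale * model(thickness, offset) - values

    res = least_squares(
        residuals,
        x0=[d0, scale0, 0.0],
        bounds=([1.0, 1e-12, -max_angle_offset_deg], [300.0, np.inf, max_angle_offset_deg]),
        xtol=1e-12,
        ftol=1e-12,
    )
    thickness, scale, offset = res.x
    rms = float(np.sqrt(np.mean(res.fun**2))) / scale
    return FresnelFitResult(
        stack=stack_template.replace_thickness(gold_layer_index, float(thickness)),
        gold_thickness_nm=float(thickness),
        intensity_scale=float(scale),
        angle_offset_deg=float(offset),
        residual_rms=rms,
        success=bool(res.success),
        message=res.message,
    )
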