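"""The bead-based penetration-depth measurement pipeline.

Mirrors the instrument's image-analysis routine: divide the p- by the
s-polarized frame to cancel illumination inhomogeneity, rescale to
reflectivity units, convert to ΔR against a background region, estimate the
background noise σ in an annulus around the bead, delineate the bead
footprint with a k·σ threshold (k = 3), convert the above-threshold pixel
count to a circle-equivalent radius r₂, and invert the sphere-chord
geometry to the detectable evanescent-field depth

    d = r₁ − sqrt(r₁² − r₂²)   (nm),

the unique depth at which a sphere of radius r₁ resting on the surface has
horizontal chord radius r₂.  (The algebraically different relation
r₁² = r₂² + (r₂ − d)² sometimes quoted for this geometry has no real
solution for small observed chords; the chord form above is the
geometrically consistent one and is verified against the forward relation
r₂ = sqrt(d(2r₁ − d)) in the test suite.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import CircleROI, SPRImage
from .optics import stack_reflectance

__all__ = [
    "BeadMeasurement",
    "ThresholdRadiusResult",
    "LinescanClasses",
    "normalize_ps",
    "ratio_to_reflectance",
    "to_delta_R",
    "background_sigma_annulus",
    "bead_radius_from_threshold",
    "depth_from_radii",
    "chord_radius_from_depth",
    "fwhm_from_profile",
    "brightfield_radius",
    "measure_bead",
    "aggregate_penetration_depths",
    "classify_linescan",
]


@dataclass
class BeadMeasurement:
    """Per-bead result: radii, inferred depth, and the threshold context."""

    r1_um: float
    r2_um: float
    depth_d_nm: float
    wavelength_nm: float
    background_sigma: float
    threshold_k: float = 3.0
    n_pixels_above: int = 0
    material: str = "bead"
    bead_id: int = 0
    flagged: bool = False

    def __post_init__(self):
        if not 0 <= self.r2_um <= self.r1_um:
            raise ValueError("need 0 <= r2 <= r1")
        if self.depth_d_nm < 0:
            raise ValueError("depth must be >= 0")
        if not self.threshold_k > 0:
            raise ValueError("threshold multiplier must be > 0")


@dataclass(frozen=True)
class LinescanClasses:
    """Three ascending ΔR thresholds splitting a linescan into four classes."""

    thresholds: tuple[float, float, float]
    labels: tuple[str, str, str, str] = (
        "substrate",
        "ECM",
        "basal cell",
        "focal adhesion",
    )

    def __post_init__(self):
        t = self.thresholds
        if not (t[0] < t[1] < t[2]):
            raise ValueError("thresholds must be strictly ascending")
        if len(self.labels) != 4:
            raise ValueError("exactly four class labels required")


def normalize_ps(
    p_image: SPRImage, s_image: SPRImage, s_floor_fraction: float = 1e-6
) -> SPRImage:
    """Element-wise p/s ratio image; cancels illumination inhomogeneity.

    Pixels where s falls below ``s_floor_fraction`` of the s-image median
    are masked (set on the returned image's ``mask``) rather than divided.
    """
    if p_image.shape != s_image.shape:
        raise ValueError("p and s images must have the same shape")
    if p_image.pixel_size_um != s_image.pixel_size_um:
        raise ValueError("p and s images must share the pixel size")
    s = s_image.pixels
    s_med = float(np.median(np.abs(s)))
    if s_med == 0:
        raise ValueError("s image is all zeros")
    floor = s_floor_fraction * s_med
    bad = np.abs(s) < floor
    ratio = np.divide(p_image.pixels, s, out=np.zeros_like(s), where=~bad)
    out = SPRImage(
        ratio, p_image.pixel_size_um, p_image.wavelength_nm, "ratio", "ratio"
    )
    out.mask = bad
    return out


def ratio_to_reflectance(ratio_image: SPRImage, s_reflectance: float) -> SPRImage:
    """Scale a p/s ratio image to reflectivity units.

    ``s_reflectance`` is the model s-polarized reflectance at the operating
    angle (from the Fresnel fit of the BFP angle scan); the conversion is
    R_p = (p/s)·R_s.
    """
    out = ratio_image.with_pixels(ratio_image.pixels * s_reflectance, "reflectance")
    out.polarization = "p"
    return out


def _roi_mask(image: SPRImage, roi) -> np.ndarray:
    if isinstance(roi, CircleROI):
        return roi.mask(image.shape, image.pixel_size_um)
    mask = np.asarray(roi)
    if mask.dtype != bool or mask.shape != image.shape:
        raise ValueError("ROI must be a CircleROI or a boolean mask of image shape")
    return mask


def to_delta_R(image: SPRImage, background_roi) -> SPRImage:
    """Subtract the background-region mean: ΔR = R₁ − R₀.

    The returned image has the background ROI mean equal to zero to machine
    precision.  ``background_roi`` is a CircleROI or boolean mask.
    """
    mask = _roi_mask(image, background_roi)
    if not mask.any():
        raise ValueError("background ROI is empty")
    r0 = float(image.pixels[mask].mean())
    out = image.with_pixels(image.pixels - r0, "delta_R")
    return out


def background_sigma_annulus(
    image: SPRImage, bead_roi: CircleROI, dilation_um: float = 10.0
) -> float:
    """Sample standard deviation of the background annulus around a bead.

    The annulus lies between the bead ROI circle and the circle whose
    *diameter* is larger by ``dilation_um`` (i.e. radius + dilation/2),
    following the instrument's analysis recipe.  The annulus must lie
    fully inside the image.
    """
    outer = bead_roi.dilated(dilation_um / 2.0)
    w, h = image.extent_um
    for side, clipped in (
        ("left", outer.cx_um - outer.radius_um < 0),
        ("right", outer.cx_um + outer.radius_um > w),
        ("top", outer.cy_um - outer.radius_um < 0),
        ("bottom", outer.cy_um + outer.radius_um > h),
    ):
        if clipped:
            raise ValueError(f"annulus clipped by the {side} image edge")
    inner_mask = bead_roi.mask(image.shape, image.pixel_size_um)
    outer_mask = outer.mask(image.shape, image.pixel_size_um)
    ring = outer_mask & ~inner_mask
    return float(np.std(image.pixels[ring], ddof=1))


@dataclass
class ThresholdRadiusResult:
    """Circle-equivalent radius from above-threshold pixel counting."""

    r2_um: float
    n_pixels_above: int
    threshold: float
    flagged: bool = False  # True when nothing exceeded the threshold


def bead_radius_from_threshold(
    image: SPRImage,
    bead_roi: CircleROI,
    sigma: float,
    k: float = 3.0,
    background_mean: float = 0.0,
    largest_component_only: bool = False,
) -> ThresholdRadiusResult:
    """SPR-apparent bead radius r₂ from the k·σ threshold pixel count.

    Counts pixels inside ``bead_roi`` with ΔR more than ``k·σ`` above the
    background mean (0 after ΔR conversion) and converts the count to the
    radius of the equal-area circle, r₂ = sqrt(N·A_pixel/π).  By default
    every above-threshold pixel counts, exactly as the instrument recipe
    counts them; ``largest_component_only`` optionally restricts to the
    largest connected blob.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    mask = bead_roi.mask(image.shape, image.pixel_size_um)
    above = mask & (image.pixels - background_mean > k * sigma)
    if largest_component_only and above.any():
        labels, n = ndimage.label(above)
        sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
        above = labels == (1 + int(np.argmax(sizes)))
    n_above = int(above.sum())
    if n_above == 0:
        warnings.warn("no pixels above threshold; returning r2 = 0", stacklevel=2)
        return ThresholdRadiusResult(0.0, 0, k * sigma, flagged=True)
    area = n_above * image.pixel_size_um**2
    return ThresholdRadiusResult(float(np.sqrt(area / np.pi)), n_above, k * sigma)


def depth_from_radii(r1_um: float, r2_um: float) -> float:
    """Detectable evanescent-field depth d (nm) from the two bead radii.

    d = r₁ − sqrt(r₁² − r₂²): the depth at which a sphere of radius r₁
    resting on the surface has horizontal chord radius r₂.
    """
    if not 0 <= r2_um <= r1_um:
        raise ValueError("need 0 <= r2 <= r1")
    return (r1_um - np.sqrt(r1_um**2 - r2_um**2)) * 1000.0


def chord_radius_from_depth(r1_um: float, d_nm: float) -> float:
    """Forward chord relation r₂ = sqrt(d·(2r₁ − d)), inverse of the above."""
    d_um = d_nm / 1000.0
    if not 0 <= d_um <= r1_um:
        raise ValueError("need 0 <= d <= r1")
    return float(np.sqrt(d_um * (2 * r1_um - d_um)))


def fwhm_from_profile(profile, pixel_size_um: float) -> float:
    """Full width at half maximum of a single-peaked 1-D profile, in μm.

    Baseline is the median of the outer quartiles of the profile; the two
    half-maximum crossings are located by linear interpolation between
    samples.  Raises when the profile does not cross half maximum on both
    sides of the peak.
    """
    y = np.asarray(profile, float)
    n = y.size
    if n < 5:
        raise ValueError("profile too short")
    q = max(n // 4, 1)
    baseline = float(np.median(np.concatenate([y[:q], y[-q:]])))
    i_peak = int(np.argmax(y))
    half = (y[i_peak] + baseline) / 2.0

    def crossing(indices):
        for i in indices:
            y0, y1 = y[i], y[i + 1]
            if (y0 - half) * (y1 - half) <= 0 and y0 != y1:
                return i + (half - y0) / (y1 - y0)
        return None

    left = crossing(range(i_peak - 1, -1, -1))
    right = crossing(range(i_peak, n - 1))
    if left is None or right is None:
        raise ValueError("profile does not cross half maximum on both sides")
    return float((right - left) * pixel_size_um)


def brightfield_radius(
    image: SPRImage, center_um: tuple[float, float], r_max_um: float | None = None
) -> float:
    """Bead radius from the dark edge ring of a bright-field image (μm).

    Builds a radial intensity profile about ``center_um`` (pixel-width
    bins) and returns the ring-centerline radius: the profile minimum,
    refined by a parabolic fit through the three bracketing bins.
    """
    px = image.pixel_size_um
    x, y = image.pixel_centers_um()
    rho = np.hypot(x - center_um[0], y - center_um[1])
    if r_max_um is None:
        r_max_um = rho.max()
    nbins = int(r_max_um / px)
    idx = (rho / px).astype(int)
    sel = idx < nbins
    sums = np.bincount(idx[sel], weights=image.pixels[sel], minlength=nbins)
    counts = np.bincount(idx[sel], minlength=nbins)
    profile = sums / np.maximum(counts, 1)
    i = int(np.argmin(profile[1 : nbins - 1])) + 1
    y0, y1, y2 = profile[i - 1 : i + 2]
    denom = y0 - 2 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return float((i + 0.5 + shift) * px)


def measure_bead(
    p_image: SPRImage,
    s_image: SPRImage,
    brightfield: SPRImage,
    bead_center_um: tuple[float, float],
    bead_roi_radius_um: float,
    s_reflectance: float,
    r1_um: float | None = None,
    k: float = 3.0,
    dilation_um: float = 10.0,
    background_roi: CircleROI | None = None,
    material: str = "bead",
    bead_id: int = 0,
) -> BeadMeasurement:
    """Run the full per-bead pipeline on one p/s/bright-field triple.

    When ``r1_um`` is not given it is measured from the bright-field ring.
    The ΔR background is the annulus itself (its mean is subtracted), so
    thresholding is relative to the local background, unless an explicit
    ``background_roi`` is supplied.
    """
    ratio = normalize_ps(p_image, s_image)
    refl = ratio_to_reflectance(ratio, s_reflectance)
    bead_roi = CircleROI(bead_center_um[0], bead_center_um[1], bead_roi_radius_um)
    if background_roi is None:
        outer = bead_roi.dilated(dilation_um / 2.0)
        bg_mask = outer.mask(refl.shape, refl.pixel_size_um) & ~bead_roi.mask(
            refl.shape, refl.pixel_size_um
        )
        delta = to_delta_R(refl, bg_mask)
    else:
        delta = to_delta_R(refl, background_roi)
    sigma = background_sigma_annulus(delta, bead_roi, dilation_um)
    thr = bead_radius_from_threshold(delta, bead_roi, sigma, k)
    if r1_um is None:
        # search the whole frame: the bright-field edge ring sits at the
        # physical radius r1, typically far outside the SPR footprint ROI
        r1_um = brightfield_radius(brightfield, bead_center_um)
    r2 = min(thr.r2_um, r1_um)  # chord cannot exceed the sphere radius
    return BeadMeasurement(
        r1_um=r1_um,
        r2_um=r2,
        depth_d_nm=depth_from_radii(r1_um, r2),
        wavelength_nm=p_image.wavelength_nm,
        background_sigma=sigma,
        threshold_k=k,
        n_pixels_above=thr.n_pixels_above,
        material=material,
        bead_id=bead_id,
        flagged=thr.flagged,
    )


def aggregate_penetration_depths(
    measurements: list[BeadMeasurement], lp_theory_nm: dict[float, float]
) -> pd.DataFrame:
    """Group bead depths by (wavelength, material) against theoretical Lp.

    Returns one row per group with the mean depth, sample SD (0 with an
    ``n=1`` flag for singleton groups), bead count, and the theoretical
    1/e penetration depth Lp and 3·Lp detection-limit columns.
    """
    if not measurements:
        raise ValueError("no measurements to aggregate")
    df = pd.DataFrame(
        {
            "wavelength_nm": [m.wavelength_nm for m in measurements],
            "material": [m.material for m in measurements],
            "depth_nm": [m.depth_d_nm for m in measurements],
        }
    )
    rows = []
    for (wl, mat), grp in df.groupby(["wavelength_nm", "material"], sort=True):
        n = len(grp)
        lp = lp_theory_nm.get(wl, np.nan)
        rows.append(
            {
                "wavelength_nm": wl,
                "material": mat,
                "mean_depth_nm": float(grp["depth_nm"].mean()),
                "sd_nm": float(grp["depth_nm"].std(ddof=1)) if n > 1 else 0.0,
                "n_beads": n,
                "single_measurement": n == 1,
                "lp_theory_nm": lp,
                "lp3_theory_nm": 3 * lp,
            }
        )
    return pd.DataFrame(rows)


def classify_linescan(profile, classes: LinescanClasses):
    """Label each ΔR sample of a linescan by its threshold interval.

    Returns ``(labels, runs)`` where ``labels`` is one class name per
    sample and ``runs`` is the sequence of contiguous ``(label, start,
    length)`` runs — the four-feature segmentation of a scan crossing
    substrate, deposited ECM, basal cell surface and focal adhesions.
    """
    y = np.asarray(profile, float)
    t = classes.thresholds
    idx = np.searchsorted(t, y, side="right")
    labels = [classes.labels[i] for i in idx]
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i - start))
            start = i
    return labels, runs
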