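"""TZP counting on equatorial confocal sections.

A granulosa cell–oocyte complex imaged at its equator shows the F-actin-rich
transzonal projections (TZPs) as bright radial streaks crossing the dark
zona pellucida. The counting procedure:

1. model the oocyte as a circle (given or fitted to the cortical signal);
2. sample the image along the closed circle lying in the middle of the zona
   (radius ``oocyte_radius + zona_thickness / 2``) by bilinear interpolation;
3. estimate the oocyte-cytoplasm background from an interior disk;
4. call every profile sample that exceeds that background and is strictly
   higher than both circular neighbours a TZP;
5. normalize the count to the oocyte diameter (TZPs per µm).

The peak rule is deliberately literal: strict inequality on both neighbours
(plateaus are not peaks) and circular indexing (the first and last samples
are adjacent). By default the profile is smoothed with a 5-sample circular
boxcar before peak calling — at the default 0.1 µm sampling that is a
0.5 µm kernel matched to the ~0.4 µm TZP width. The bare rule is extremely
sensitive to uncorrelated single-sample noise; real acquisitions arrive
pre-blurred by the microscope optics, which synthetic or deconvolved inputs
are not. Set ``smooth_width=0`` to apply the bare rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import ImagePlane

__all__ = [
    "OocyteModel",
    "RadialProfile",
    "TZPCountResult",
    "fit_oocyte_circle",
    "estimate_background",
    "extract_equatorial_profile",
    "smooth_profile",
    "count_tzp_peaks",
    "normalize_tzp_count",
    "count_equatorial_tzps",
]


@dataclass(frozen=True)
class OocyteModel:
    """Circular (2D) or spherical (3D) oocyte reference geometry.

    center is ``(y, x)`` or ``(z, y, x)`` in µm; ``radius`` is the oocyte
    radius in µm (the zona pellucida then spans
    ``[radius, radius + zona_thickness]``).
    """

    center: tuple[float, ...]
    radius: float
    zona_thickness: float = 7.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if len(self.center) not in (2, 3):
            raise ValueError("center must be (y, x) or (z, y, x)")
        if not self.radius > 0:
            raise ValueError("oocyte radius must be > 0 µm")
        if not self.zona_thickness > 0:
            raise ValueError("zona_thickness must be > 0 µm")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def mid_zona_radius(self) -> float:
        """Radius of the counting circle, in the middle of the zona."""
        return self.radius + self.zona_thickness / 2.0


@dataclass
class RadialProfile:
    """Closed circular intensity profile at a fixed radius around the oocyte."""

    samples: np.ndarray
    arc_positions: np.ndarray  # µm along the circle, strictly increasing
    source_radius: float       # µm
    circular: bool = True

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.arc_positions = np.asarray(self.arc_positions, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 8:
            raise ValueError("a circular profile needs at least 8 samples")
        if self.arc_positions.shape != self.samples.shape:
            raise ValueError("arc_positions must match samples")
        if np.any(np.diff(self.arc_positions) <= 0):
            raise ValueError("arc positions must be strictly increasing")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class TZPCountResult:
    """Peak count on one equatorial section, raw and diameter-normalized."""

    raw_count: int
    background: float
    oocyte_diameter: float
    normalized_count: float  # TZPs per µm of oocyte diameter
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def as_record(self) -> dict:
        return {
            "raw_count": self.raw_count,
            "background": self.background,
            "oocyte_diameter_um": self.oocyte_diameter,
            "tzp_per_um": self.normalized_count,
        }


def fit_oocyte_circle(image: ImagePlane, zona_thickness: float = 7.0,
                      percentile: float = 99.0) -> OocyteModel:
    """Least-squares circle fit (Kåsa) to the brightest cortical pixels.

    Intended for images where the oocyte cortex is the dominant bright ring
    (phalloidin channel). Returns an :class:`OocyteModel` in µm coordinates.
    """
    img = image.intensities
    thr = np.percentile(img, percentile)
    ys, xs = np.nonzero(img >= thr)
    if ys.size < 3:
        raise ValueError("too few bright pixels to fit a circle")
    y = ys * image.pixel_size
    x = xs * image.pixel_size
    # Kåsa fit: minimize ||a*y + b*x + c - (x^2+y^2)||
    A = np.column_stack([y, x, np.ones_like(x)])
    b = x**2 + y**2
    (ay, ax, c), *_ = np.linalg.lstsq(A, b, rcond=None)
    cy, cx = ay / 2.0, ax / 2.0
    radius = float(np.sqrt(c + cy**2 + cx**2))
    return OocyteModel(center=(float(cy), float(cx)), radius=radius,
                       zona_thickness=zona_thickness)


def estimate_background(image: ImagePlane, oocyte: OocyteModel,
                        method: str = "median", fraction: float = 0.7) -> float:
    """Oocyte-cytoplasm background: summary over an interior disk.

    The disk has radius ``fraction * oocyte.radius`` (default 0.7) so the
    bright actin cortex is excluded. ``method`` is ``"median"`` (default,
    robust to interior texture) or ``"mean"``.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"unknown background method {method!r}")
    if len(oocyte.center) != 2:
        raise ValueError("estimate_background expects a 2D oocyte model")
    cy, cx = (c / image.pixel_size for c in oocyte.center)
    r_px = fraction * oocyte.radius / image.pixel_size
    ny, nx = image.shape
    if (cy - r_px < -0.5 or cx - r_px < -0.5
            or cy + r_px > ny - 0.5 or cx + r_px > nx - 0.5):
        raise ValueError("oocyte interior disk extends beyond the image")
    yy, xx = np.ogrid[:ny, :nx]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    if not mask.any():
        raise ValueError("oocyte interior ROI is empty")
    values = image.intensities[mask]
    return float(np.median(values) if method == "median" else np.mean(values))


def extract_equatorial_profile(image: ImagePlane, oocyte: OocyteModel,
                               sampling_step: float | None = None) -> RadialProfile:
    """Sample the image along the mid-zona circle at uniform arc steps.

    ``sampling_step`` is the arc length between samples in µm; default is one
    pixel. Intensities are bilinearly interpolated. Raises if the circle
    leaves the image.
    """
    if len(oocyte.center) != 2:
        raise ValueError("extract_equatorial_profile expects a 2D oocyte model")
    if sampling_step is None:
        sampling_step = image.pixel_size
    if not sampling_step > 0:
        raise ValueError("sampling_step must be > 0 µm")
    radius = oocyte.mid_zona_radius
    circumference = 2.0 * np.pi * radius
    n = int(np.ceil(circumference / sampling_step))
    if n < 8:
        raise ValueError("sampling_step too coarse: fewer than 8 samples")
    theta = 2.0 * np.pi * np.arange(n) / n
    cy, cx = oocyte.center
    y = (cy + radius * np.sin(theta)) / image.pixel_size
    x = (cx + radius * np.cos(theta)) / image.pixel_size
    ny, nx = image.shape
    if y.min() < 0 or x.min() < 0 or y.max() > ny - 1 or x.max() > nx - 1:
        raise ValueError("mid-zona circle exits the image bounds")
    samples = ndimage.map_coordinates(image.intensities.astype(float),
                                      np.vstack([y, x]), order=1)
    arc = theta * radius
    return RadialProfile(samples=samples, arc_positions=arc, source_radius=radius)


def smooth_profile(profile: RadialProfile, width: int = 3) -> RadialProfile:
    """Circular boxcar smoothing of a profile; ``width`` must be odd, ≥ 1.

    ``width=1`` returns the profile unchanged.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("smoothing width must be an odd integer >= 1")
    if width == 1:
        return profile
    kernel = np.ones(width) / width
    smoothed = ndimage.convolve1d(profile.samples, kernel, mode="wrap")
    return RadialProfile(samples=smoothed, arc_positions=profile.arc_positions,
                         source_radius=profile.source_radius)


def count_tzp_peaks(profile: RadialProfile | np.ndarray, background: float) -> np.ndarray:
    """Indices of profile samples counted as TZPs.

    A sample ``i`` is a peak iff ``samples[i] > background`` and
    ``samples[i]`` is strictly greater than both circular neighbours
    (``i−1`` and ``i+1`` modulo the profile length). Plateaus therefore
    never count; at most every second sample can be a peak.

    Accepts a :class:`RadialProfile` or any 1D circular sample array with
    at least 3 samples.
    """
    s = profile.samples if isinstance(profile, RadialProfile) else np.asarray(profile, dtype=float)
    if s.size < 3:
        raise ValueError("profile must have at least 3 samples")
    left = np.roll(s, 1)
    right = np.roll(s, -1)
    is_peak = (s > background) & (s > left) & (s > right)
    return np.nonzero(is_peak)[0]


def normalize_tzp_count(raw_count: int, oocyte_diameter: float) -> float:
    """TZP count per µm of oocyte diameter."""
    if not oocyte_diameter > 0:
        raise ValueError("oocyte diameter must be > 0 µm")
    if raw_count < 0:
        raise ValueError("raw_count must be >= 0")
    return raw_count / oocyte_diameter


def count_equatorial_tzps(
    image: ImagePlane,
    oocyte: OocyteModel,
    sampling_step: float | None = None,
    background: float | None = None,
    background_method: str = "median",
    smooth_width: int = 5,
) -> TZPCountResult:
    """Full equatorial counting pipeline on one section.

    Background estimation → mid-zona circular profile → optional boxcar
    smoothing → strict local-maximum peak calling → diameter normalization.
    Pass ``smooth_width=0`` (or 1) to skip smoothing, or ``background=`` to
    override the cytoplasm estimate.
    """
    if background is None:
        background = estimate_background(image, oocyte, method=background_method)
    profile = extract_equatorial_profile(image, oocyte, sampling_step)
    if smooth_width and smooth_width > 1:
        profile = smooth_profile(profile, smooth_width)
    peaks = count_tzp_peaks(profile, background)
    raw = int(peaks.size)
    return TZPCountResult(
        raw_count=raw,
        background=float(background),
        oocyte_diameter=oocyte.diameter,
        normalized_count=normalize_tzp_count(raw, oocyte.diameter),
        peak_indices=peaks,
    )
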