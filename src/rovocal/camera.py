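"""Camera geometry: field-of-view estimation and flat-port refraction.

A rotating video lander images through a flat window (flat port).  In air
the lens has its nominal full horizontal field of view (FOV); in water the
rays refract at the window, so the same sensor span covers a narrower
angle.  For a thin flat port, Snell's law applied to the half-angle gives

    sin(theta_air / 2) = n_water * sin(theta_water / 2)

The FOV itself is estimated photogrammetrically from an image of a test
pattern at known distance D:

    theta = 2 * arctan( N_px * dx_cm / (2 * D * dx_pix) )

where ``N_px`` is the horizontal image size in pixels, ``dx_cm`` the
physical width between two reference edges of the pattern and ``dx_pix``
the same width measured in the image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CameraModel",
    "SpanMeasurement",
    "InvalidMeasurementError",
    "fov_from_span",
    "air_to_water_fov",
    "water_to_air_fov",
    "megapixels",
    "focal_length_px",
    "DEFAULT_N_WATER",
]

#: Refractive index of seawater used throughout unless overridden.  This
#: single value reproduces both whole-degree conversions quoted for the
#: instrument (82 deg air -> 59 deg water, 60 deg water -> 84 deg air).
DEFAULT_N_WATER = 1.34


class InvalidMeasurementError(ValueError):
    """A span measurement violates its physical preconditions."""


@dataclass(frozen=True)
class CameraModel:
    """Pixel format and nominal optics of a camera.

    Parameters
    ----------
    width_px, height_px : int
        Image dimensions in pixels (``width_px`` is the horizontal size
        that enters the FOV formula).
    fov_air_deg : float
        Nominal full horizontal field of view in air, degrees.
    n_water : float
        Refractive index of the immersion water, default seawater (1.34).
    """

    width_px: int
    height_px: int
    fov_air_deg: float
    n_water: float = DEFAULT_N_WATER

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("pixel dimensions must be positive")
        if not 0.0 < self.fov_air_deg < 180.0:
            raise ValueError("fov_air_deg must lie in (0, 180)")
        if self.n_water < 1.0:
            raise ValueError("n_water must be >= 1")

    @property
    def fov_water_deg(self) -> float:
        """In-water FOV implied by the nominal air FOV and n_water."""
        return air_to_water_fov(self.fov_air_deg, self.n_water)

    @property
    def megapixels(self) -> float:
        return megapixels(self.width_px, self.height_px)


@dataclass(frozen=True)
class SpanMeasurement:
    """A measured horizontal span of the test pattern.

    ``dx_cm`` is the physical distance between the two reference edges of
    the pattern, ``dx_pix`` the same distance in the image, and
    ``distance_cm`` the camera-to-pattern distance D.
    """

    dx_cm: float
    dx_pix: float
    distance_cm: float

    def __post_init__(self) -> None:
        if self.dx_cm < 0:
            raise InvalidMeasurementError("dx_cm must be non-negative")
        if self.dx_pix <= 0:
            raise InvalidMeasurementError("dx_pix must be positive")
        if self.distance_cm <= 0:
            raise InvalidMeasurementError("distance_cm must be positive")


def fov_from_span(camera: CameraModel, span: SpanMeasurement) -> float:
    """Full horizontal FOV (degrees) from a measured pattern span.

    Evaluates ``theta = 2*arctan(width_px * dx_cm / (2 * D * dx_pix))``.
    The measured span is scaled up to the full sensor width, so the span
    need not fill the image.
    """
    ratio = camera.width_px * span.dx_cm / (2.0 * span.distance_cm * span.dx_pix)
    return math.degrees(2.0 * math.atan(ratio))


def air_to_water_fov(fov_air_deg: float, n_water: float = DEFAULT_N_WATER) -> float:
    """Convert a full FOV in air to the FOV behind a flat port in water.

    Snell bend on the half-angle: ``theta_w = 2*asin(sin(theta_a/2)/n)``.
    """
    if not 0.0 <= fov_air_deg < 180.0:
        raise ValueError("fov_air_deg must lie in [0, 180)")
    if n_water < 1.0:
        raise ValueError("n_water must be >= 1")
    half = math.radians(fov_air_deg) / 2.0
    return math.degrees(2.0 * math.asin(math.sin(half) / n_water))


def water_to_air_fov(fov_water_deg: float, n_water: float = DEFAULT_N_WATER) -> float:
    """Convert an in-water FOV back to the equivalent FOV in air.

    Raises
    ------
    ValueError
        If ``n_water*sin(theta_w/2) > 1`` (no real air angle exists; the
        flat port would require total internal reflection).
    """
    if not 0.0 <= fov_water_deg < 180.0:
        raise ValueError("fov_water_deg must lie in [0, 180)")
    if n_water < 1.0:
        raise ValueError("n_water must be >= 1")
    half = math.radians(fov_water_deg) / 2.0
    s = n_water * math.sin(half)
    if s > 1.0:
        raise ValueError(
            f"n*sin(fov/2) = {s:.6f} > 1: no air-side angle exists for "
            f"fov_water={fov_water_deg} deg at n={n_water}"
        )
    return math.degrees(2.0 * math.asin(s))


def megapixels(width_px: int, height_px: int) -> float:
    """Pixel count in megapixels, reported to two decimals."""
    if width_px < 0 or height_px < 0:
        raise ValueError("pixel dimensions must be non-negative")
    return round(width_px * height_px / 1e6, 2)


def focal_length_px(camera: CameraModel, fov_deg: float | None = None) -> float:
    """Pinhole focal length in pixels for a given full horizontal FOV.

    ``f = width_px / (2 * tan(fov/2))``.  Defaults to the camera's nominal
    air FOV; pass the in-water FOV for submerged scenes.
    """
    fov = camera.fov_air_deg if fov_deg is None else fov_deg
    return camera.width_px / (2.0 * math.tan(math.radians(fov) / 2.0))
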