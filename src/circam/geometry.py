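"""Closed-form sensor/lens design math for circular-image cameras.

A round lens illuminates a circular *image field* (IF) on the image plane.
A conventional rectangular sensor chip inscribed in that circle crops away
the four circular segments outside its active area; the functions here
quantify that waste, the effective per-axis fields of view of the cropped
rectangle, and the *rematch* calculus: choosing a larger chip whose height
equals the IF diameter so that the full circular image is captured, together
with the pixel-density bookkeeping that choice implies.

Conventions
-----------
* Lengths are unit-free but must be consistent within a call. Optical
  formats ("1/4 inch") are treated as literal diagonal lengths; real die
  sizes differ from the nominal format and honouring datasheets is out of
  scope here.
* Angles are degrees at every public interface; radians are used only
  inside computations.
* The screen (aspect) ratio eta is width divided by height (4:3 -> 4/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Sequence

from .errors import DomainError, NoSuitableFormatError

__all__ = [
    "AspectRatio",
    "SensorSpec",
    "LensSpec",
    "RematchResult",
    "STANDARD_FORMATS",
    "chip_dimensions",
    "diagonal_fov",
    "effective_fov",
    "crop_waste_fraction",
    "rematch_min_diagonal",
    "select_standard_format",
    "rematch_pixel_plan",
    "rematch",
    "round_half_up",
]

#: Common optical formats (nominal diagonal, inches), ascending.
STANDARD_FORMATS: tuple[float, ...] = tuple(
    sorted(
        1 / x
        for x in (7, 6, 5, 4.5, 4, 3.2, 3, 2.7, 2.5, 2, 1.8, 1.5, 1)
    )
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed design tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AspectRatio:
    """Sensor screen ratio, width over height.

    Parameters
    ----------
    eta
        Width:height ratio as a positive real (4:3 sensors have eta = 4/3).
    """

    eta: float

    def __post_init__(self) -> None:
        if not self.eta > 0:
            raise DomainError(f"aspect ratio must be positive, got {self.eta}")

    @classmethod
    def parse(cls, text: str | float) -> "AspectRatio":
        """Parse ``"W:H"``, ``"W/H"`` or a plain number into an aspect ratio."""
        if isinstance(text, (int, float)):
            return cls(float(text))
        s = str(text).strip().replace(":", "/")
        try:
            return cls(float(Fraction(s)))
        except (ValueError, ZeroDivisionError) as exc:
            raise DomainError(f"cannot parse aspect ratio {text!r}") from exc

    def __float__(self) -> float:
        return self.eta


def _eta(aspect: AspectRatio | float) -> float:
    eta = float(aspect)
    if not eta > 0:
        raise DomainError(f"aspect ratio must be positive, got {eta}")
    return eta


@dataclass(frozen=True)
class SensorSpec:
    """Rectangular image sensor chip.

    Parameters
    ----------
    diagonal
        Diagonal length of the active area (any consistent length unit).
    aspect
        Screen ratio (width:height).
    pixel_density
        Pixels per unit length (sigma); datasheets usually quote its
        reciprocal as the "pixel size".
    """

    diagonal: float
    aspect: AspectRatio
    pixel_density: float = 1.0

    def __post_init__(self) -> None:
        if not self.diagonal > 0:
            raise DomainError(f"diagonal must be positive, got {self.diagonal}")
        if not self.pixel_density > 0:
            raise DomainError(
                f"pixel density must be positive, got {self.pixel_density}"
            )

    @property
    def height(self) -> float:
        return self.diagonal / math.hypot(1.0, self.aspect.eta)

    @property
    def width(self) -> float:
        return self.aspect.eta * self.height

    @property
    def pixel_count(self) -> float:
        """Total pixels N = eta * h^2 * sigma^2."""
        return self.aspect.eta * self.height**2 * self.pixel_density**2


@dataclass(frozen=True)
class LensSpec:
    """Round lens: focal length and the diameter of its circular image field."""

    focal_length: float
    image_field_diameter: float

    def __post_init__(self) -> None:
        if not self.focal_length > 0:
            raise DomainError("focal length must be positive")
        if not self.image_field_diameter > 0:
            raise DomainError("image field diameter must be positive")


@dataclass(frozen=True)
class RematchResult:
    """Outcome of a chip-lens rematch design.

    Attributes
    ----------
    min_diagonal
        Smallest chip diagonal whose height equals the IF diameter.
    selected_format
        Chosen catalog format (same units), >= min_diagonal.
    pixel_density_2
        Pixel density of the rematched chip (sigma2).
    pixel_ratio
        N2/N1, total pixels of the rematched chip over the original.
    resolution_change
        Fractional change of linear pixel density, sigma2/sigma1 - 1.
    """

    min_diagonal: float
    selected_format: float
    pixel_density_2: float
    pixel_ratio: float
    resolution_change: float

    def to_dict(self) -> dict:
        return {
            "min_diagonal": self.min_diagonal,
            "selected_format": self.selected_format,
            "pixel_density_2": self.pixel_density_2,
            "pixel_ratio": self.pixel_ratio,
            "resolution_change": self.resolution_change,
        }


def chip_dimensions(
    diagonal: float, aspect: AspectRatio | float
) -> tuple[float, float]:
    """Width and height of a chip from its diagonal and screen ratio.

    Solves h * sqrt(1 + eta^2) = d, w = eta * h.
    """
    eta = _eta(aspect)
    if not diagonal > 0:
        raise DomainError(f"diagonal must be positive, got {diagonal}")
    height = diagonal / math.hypot(1.0, eta)
    return eta * height, height


def diagonal_fov(diagonal: float, focal_length: float) -> float:
    """Pinhole diagonal field of view, 2*atan(d / 2f), in degrees."""
    if not (diagonal > 0 and focal_length > 0):
        raise DomainError("diagonal and focal length must be positive")
    return math.degrees(2.0 * math.atan2(diagonal, 2.0 * focal_length))


def effective_fov(
    fov_diagonal_deg: float, aspect: AspectRatio | float
) -> tuple[float, float]:
    """Horizontal and vertical FOV of the rectangle cropped from the IF.

    For a sensor of ratio eta whose diagonal subtends ``fov_diagonal_deg``,
    the per-axis FOVs follow from the width/diagonal and height/diagonal
    ratios applied to the tangent of the half-angle:

        fov_h = 2*atan( (eta / sqrt(1+eta^2)) * tan(fov_d / 2) )
        fov_v = 2*atan( (1   / sqrt(1+eta^2)) * tan(fov_d / 2) )

    Both are strictly smaller than the diagonal FOV. Degrees in, degrees out.
    """
    eta = _eta(aspect)
    if not 0 < fov_diagonal_deg < 180:
        raise DomainError(
            f"diagonal FOV must be in (0, 180) degrees, got {fov_diagonal_deg}"
        )
    t = math.tan(math.radians(fov_diagonal_deg) / 2.0)
    s = math.hypot(1.0, eta)
    fov_h = math.degrees(2.0 * math.atan(eta / s * t))
    fov_v = math.degrees(2.0 * math.atan(1.0 / s * t))
    return fov_h, fov_v


def crop_waste_fraction(aspect: AspectRatio | float) -> float:
    """Fraction of the circular image field lost to a rectangular crop.

    The largest inscribed eta-rectangle has its diagonal on the circle
    diameter, so its area over the circle area is 4*eta / (pi*(1+eta^2))
    and the wasted fraction is one minus that. 0.3888... for 4:3,
    0.4559... for 16:9.
    """
    eta = _eta(aspect)
    return 1.0 - 4.0 * eta / (math.pi * (1.0 + eta * eta))


def rematch_min_diagonal(d1: float, aspect: AspectRatio | float) -> float:
    """Smallest rematched-chip diagonal capturing the full circular field.

    The IF diameter equals the original chip diagonal ``d1``; the rematched
    chip must have height >= d1, i.e. diagonal >= d1 * sqrt(1 + eta^2).
    """
    eta = _eta(aspect)
    if not d1 > 0:
        raise DomainError(f"d1 must be positive, got {d1}")
    return d1 * math.hypot(1.0, eta)


def select_standard_format(
    d_min: float, catalog: Sequence[float] = STANDARD_FORMATS
) -> float:
    """Smallest catalog format (ascending list of diagonals) >= ``d_min``."""
    if not catalog:
        raise NoSuitableFormatError("empty format catalog")
    # tiny relative slack: 1/4 must match d_min = 5/20 computed in floats
    tol = 1e-12 * max(abs(d_min), 1.0)
    for d in catalog:
        if d >= d_min - tol:
            return d
    raise NoSuitableFormatError(
        f"no catalog format >= {d_min} (largest is {catalog[-1]})"
    )


def rematch_pixel_plan(
    sigma1: float, aspect: AspectRatio | float, mode: str = "preserve_density"
) -> tuple[float, float]:
    """Pixel density sigma2 and pixel-count ratio N2/N1 after a rematch.

    Two scenarios for choosing the rematched chip's pixel density:

    ``preserve_density``
        sigma2 = sigma1; the chip area grows by (1+eta^2), so
        N2/N1 = 1 + eta^2 (2.78 for 4:3).
    ``equal_count``
        The circular region of the rematched chip holds exactly N1 pixels:
        sigma2 = sigma1 * sqrt(4*eta / (pi*(1+eta^2))) (0.78*sigma1 for 4:3,
        a 22% linear-resolution reduction) and N2/N1 = 4*eta/pi (1.69 for 4:3).

    Returns
    -------
    (sigma2, pixel_ratio)
    """
    eta = _eta(aspect)
    if not sigma1 > 0:
        raise DomainError(f"sigma1 must be positive, got {sigma1}")
    if mode == "preserve_density":
        sigma2 = sigma1
        ratio = 1.0 + eta * eta
    elif mode == "equal_count":
        sigma2 = sigma1 * math.sqrt(4.0 * eta / (math.pi * (1.0 + eta * eta)))
        ratio = (1.0 + eta * eta) * (sigma2 / sigma1) ** 2
    else:
        raise DomainError(
            f"unknown mode {mode!r}: expected 'preserve_density' or 'equal_count'"
        )
    return sigma2, ratio


def rematch(
    d1: float,
    aspect: AspectRatio | float,
    sigma1: float = 1.0,
    mode: str = "preserve_density",
    catalog: Sequence[float] = STANDARD_FORMATS,
) -> RematchResult:
    """Full rematch design: minimum diagonal, catalog pick, pixel plan."""
    d_min = rematch_min_diagonal(d1, aspect)
    fmt = select_standard_format(d_min, catalog)
    sigma2, ratio = rematch_pixel_plan(sigma1, aspect, mode)
    return RematchResult(
        min_diagonal=d_min,
        selected_format=fmt,
        pixel_density_2=sigma2,
        pixel_ratio=ratio,
        resolution_change=sigma2 / sigma1 - 1.0,
    )
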