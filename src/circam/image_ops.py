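"""Pixel-level operations for circular-image cameras.

Circular masking with constant fill (the storage trick: pre-writing a
constant into the dead corners before compression), undistortion to a
chosen output projection, re-levelling rotation with retention accounting,
and the inscribed-rectangle geometry behind the rectangular-crop loss.

Conventions
-----------
* Images are numpy uint8 arrays, (H, W) grayscale or (H, W, 3) RGB.
* Pixel (i, j) has continuous centre (j + 0.5, i + 0.5), origin top-left,
  x right, y down.
* Positive rotation angles turn the displayed image counter-clockwise.
* Fill value defaults to 0 everywhere (mask, rotation, out-of-field).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .distortion import RadialPolynomialModel
from .errors import DomainError
from .geometry import AspectRatio, _eta

__all__ = [
    "CircularDomain",
    "RectangularDomain",
    "load_image",
    "save_image",
    "apply_circular_mask",
    "storage_gain",
    "undistort_image",
    "rotate_relevel",
    "largest_inscribed_rect_fraction",
]


@dataclass(frozen=True)
class CircularDomain:
    """Circular capture region: centre (cx, cy) and radius, pixels."""

    center: tuple[float, float]
    radius: float

    kind = "circular"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise DomainError(f"radius must be >= 0, got {self.radius}")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask for (N, 2) points (x, y) inside the disk."""
        p = np.atleast_2d(points) - np.asarray(self.center)
        return np.hypot(p[:, 0], p[:, 1]) <= self.radius


@dataclass(frozen=True)
class RectangularDomain:
    """Axis-aligned rectangular capture region centred at (cx, cy), pixels."""

    center: tuple[float, float]
    width: float
    height: float

    kind = "rectangular"

    def __post_init__(self) -> None:
        if self.width < 0 or self.height < 0:
            raise DomainError("width/height must be >= 0")

    @classmethod
    def inscribed_in(
        cls, circle: CircularDomain, aspect: AspectRatio | float
    ) -> "RectangularDomain":
        """Largest aspect-eta rectangle inscribed in ``circle``.

        Its diagonal equals the circle diameter — the traditional
        rectangular image domain cut from a circular image field.
        """
        eta = _eta(aspect)
        h = 2.0 * circle.radius / math.hypot(1.0, eta)
        return cls(center=circle.center, width=eta * h, height=h)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points) - np.asarray(self.center)
        return (np.abs(p[:, 0]) <= self.width / 2.0) & (
            np.abs(p[:, 1]) <= self.height / 2.0
        )


def load_image(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode not in ("L", "RGB"):
        img = img.convert("RGB")
    return np.asarray(img)


def save_image(img: np.ndarray, path: str | Path, quality: int = 90) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path, quality=quality)


def _pixel_center_grid(h: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.arange(w) + 0.5
    y = np.arange(h) + 0.5
    return np.meshgrid(x, y)


def apply_circular_mask(
    img: np.ndarray, circle: CircularDomain, fill: int = 0
) -> np.ndarray:
    """Set pixels whose centre lies outside the circle to ``fill``.

    Pixels inside are untouched (the operation is idempotent). The circle
    centre must lie within the raster.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    cx, cy = circle.center
    if not (0 <= cx <= w and 0 <= cy <= h):
        raise DomainError(f"circle centre {circle.center} outside {w}x{h} raster")
    gx, gy = _pixel_center_grid(h, w)
    outside = np.hypot(gx - cx, gy - cy) > circle.radius
    out = img.copy()
    out[outside] = fill
    return out


def _encode_bytes(img: np.ndarray, codec: str, quality: int) -> int:
    codec = codec.upper()
    buf = io.BytesIO()
    pil = Image.fromarray(np.asarray(img, dtype=np.uint8))
    if codec == "PNG":
        pil.save(buf, format="PNG")
    elif codec == "JPEG":
        pil.save(buf, format="JPEG", quality=quality)
    else:
        raise DomainError(f"unsupported codec {codec!r}: use 'PNG' or 'JPEG'")
    return buf.getbuffer().nbytes


def storage_gain(
    img: np.ndarray,
    circle: CircularDomain,
    codec: str = "PNG",
    quality: int = 90,
    fill: int = 0,
) -> float:
    """Compressed-size ratio masked/original for the given codec.

    Pre-writing a constant into the region outside the circular image
    field makes that region compress to almost nothing, so for natural
    images with non-trivial corner content the ratio is below 1.
    """
    masked = apply_circular_mask(img, circle, fill=fill)
    return _encode_bytes(masked, codec, quality) / _encode_bytes(img, codec, quality)


def _inverse_fov_table(
    model: RadialPolynomialModel, n: int = 4096
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled (half-angle -> rho) table; half-angle strictly increasing."""
    rho = np.linspace(0.0, model.rho_max, n)
    theta = np.arctan2(rho, model._f(rho))
    return theta, rho


def undistort_image(
    model: RadialPolynomialModel,
    img: np.ndarray,
    projection: str = "stereographic",
    out_focal: float | None = None,
    out_size: tuple[int, int] | None = None,
    fill: int = 0,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Resample a distorted image into a chosen output projection.

    Inverse mapping: each output pixel at radius r from the output centre
    is converted to an incidence angle theta (stereographic:
    theta = 2*atan(r / 2F); rectilinear: theta = atan(r / F), F the output
    focal length in pixels), theta is converted to an input radius rho by
    inverting the model's per-radius FOV, and the input is sampled
    bilinearly at that radius along the same azimuth. Output pixels whose
    angle exceeds the model's half-FOV take the fill value. A rectilinear
    output can only ever request angles below 90 degrees, so a beyond-
    hemisphere source is simply trimmed to the representable cone.

    For a radially symmetric model a circular-support input yields a
    circular-support output (re-levelling-friendly: no crop needed).
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    if out_size is None:
        out_h, out_w = h, w
    else:
        out_w, out_h = out_size
    if out_focal is None:
        out_focal = float(model._f(0.0))
    if not out_focal > 0:
        raise DomainError("out_focal must be positive")
    cx, cy = model.center
    if not (0 <= cx <= w and 0 <= cy <= h):
        raise DomainError("model centre outside input raster")

    gx, gy = _pixel_center_grid(out_h, out_w)
    dx = gx - out_w / 2.0
    dy = gy - out_h / 2.0
    r = np.hypot(dx, dy)
    if projection == "stereographic":
        theta = 2.0 * np.arctan(r / (2.0 * out_focal))
    elif projection == "rectilinear":
        theta = np.arctan(r / out_focal)
    else:
        raise DomainError(
            f"unknown projection {projection!r}: "
            "use 'stereographic' or 'rectilinear'"
        )
    theta_tab, rho_tab = _inverse_fov_table(model)
    valid = theta <= theta_tab[-1]
    rho = np.interp(theta, theta_tab, rho_tab)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, rho / np.where(r > 0, r, 1.0), 0.0)
    x_in = cx + scale * dx
    y_in = cy + scale * dy
    out = _resample(img, x_in, y_in, interpolation, fill)
    out[~valid] = fill
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _resample(
    img: np.ndarray,
    x_in: np.ndarray,
    y_in: np.ndarray,
    interpolation: str,
    fill: int,
) -> np.ndarray:
    """Sample ``img`` at continuous coordinates (pixel-centre convention).

    Coordinates are clamped to the data domain for sampling and an
    explicit half-pixel in-bounds mask decides fill, so that points an
    epsilon beyond the last pixel centre still read the edge pixel
    instead of collapsing to the fill value.
    """
    order = {"bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise DomainError(f"unknown interpolation {interpolation!r}")
    h, w = img.shape[:2]
    iy = y_in - 0.5
    ix = x_in - 0.5
    inside = (iy >= -0.5) & (iy <= h - 0.5) & (ix >= -0.5) & (ix <= w - 0.5)
    coords = np.stack([np.clip(iy, 0, h - 1), np.clip(ix, 0, w - 1)])

    def _sample(plane: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            plane.astype(float), coords, order=order, mode="nearest"
        )

    if img.ndim == 2:
        out = _sample(img)
        out[~inside] = fill
    else:
        out = np.stack([_sample(img[..., c]) for c in range(img.shape[2])], axis=-1)
        out[~inside] = fill
    return out


def largest_inscribed_rect_fraction(
    aspect: AspectRatio | float, angle_deg: float
) -> float:
    """Area fraction kept when re-levelling a rectangular image by rotation.

    The largest axis-aligned rectangle of the same aspect ratio inscribed
    in an eta-rectangle rotated by ``angle_deg`` is a uniform scaling of
    the original by k = 1 / (cos a + max(eta, 1/eta) * sin a); the kept
    area fraction is k^2. Continuous on [0, 90] degrees, equal to 1 at 0.
    """
    eta = _eta(aspect)
    if not 0 <= angle_deg <= 90:
        raise DomainError(f"angle must be in [0, 90] degrees, got {angle_deg}")
    a = math.radians(angle_deg)
    k = 1.0 / (math.cos(a) + max(eta, 1.0 / eta) * math.sin(a))
    return k * k


def _fold_angle(angle_deg: float) -> float:
    """Fold any angle to the equivalent re-levelling angle in [0, 90]."""
    a = abs(angle_deg) % 180.0
    return min(a, 180.0 - a)


def rotate_relevel(
    img: np.ndarray,
    angle_deg: float,
    domain: CircularDomain | RectangularDomain,
    fill: int = 0,
    interpolation: str = "bilinear",
) -> tuple[np.ndarray, float]:
    """Rotate about the domain centre and account for retained content.

    Circular domain: rotation maps the disk onto itself, so nothing needs
    cropping and the retained fraction is exactly 1.0. Rectangular domain:
    the output is cropped to the largest same-aspect axis-aligned
    rectangle inscribed in the rotated rectangle, and the retained
    fraction is that rectangle's area over the original's.

    Returns ``(rotated_image, retained_fraction)``.
    """
    img = np.asarray(img)
    if abs(angle_deg) > 180:
        raise DomainError(f"|angle| must be <= 180 degrees, got {angle_deg}")
    h, w = img.shape[:2]
    cx, cy = domain.center
    a = math.radians(angle_deg)
    # inverse map: displayed-CCW rotation; x right, y down
    m = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
    gx, gy = _pixel_center_grid(h, w)
    rel = np.stack([gx - cx, gy - cy])
    src = np.tensordot(m, rel, axes=1)
    out = _resample(img, src[0] + cx, src[1] + cy, interpolation, fill)
    out = np.clip(np.rint(out), 0, 255).astype(np.uint8)

    if domain.kind == "circular":
        return out, 1.0

    frac = largest_inscribed_rect_fraction(
        domain.width / domain.height, _fold_angle(angle_deg)
    )
    k = math.sqrt(frac)
    half_w = k * domain.width / 2.0
    half_h = k * domain.height / 2.0
    j0 = max(0, int(math.ceil(cx - half_w - 0.5)))
    j1 = min(w, int(math.floor(cx + half_w - 0.5)) + 1)
    i0 = max(0, int(math.ceil(cy - half_h - 0.5)))
    i1 = min(h, int(math.floor(cy + half_h - 0.5)) + 1)
    return out[i0:i1, j0:j1], frac
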