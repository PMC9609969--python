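"""Polynomial radial (omnidirectional) camera model.

Wide-angle and fisheye lenses are well described by a radially symmetric
mapping: a scene ray through the optical centre at angle theta from the
optical axis lands on the sensor at radial distance rho from the image
centre, where rho and theta are linked through a polynomial

    f(rho) = a0 + a2*rho^2 + a3*rho^3 + ... + an*rho^n

with the ray direction proportional to (u, v, f(rho)), rho = sqrt(u^2+v^2).
The linear term is fixed at zero so the mapping is smooth at the centre;
a0 > 0 keeps the optical axis forward-facing. This is the standard
omnidirectional-camera parameterisation: f can go negative at large rho
for lenses that see beyond a hemisphere, and the per-radius field of view

    FOV(rho) = 2 * atan2(rho, f(rho))

then exceeds 180 degrees. A constant polynomial f(rho) = a0 is exactly the
pinhole model with focal length a0 (FOV(rho) = 2*atan(rho/a0)).

Coefficients and radii are in pixels; angles are degrees at the public API.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    CalibrationError,
    DomainError,
    FovNotReachableError,
    OutsideFieldError,
)

__all__ = [
    "RadialPolynomialModel",
    "CorrespondenceSet",
    "CalibrationResult",
    "project_direction",
    "project_directions",
    "back_project",
    "fov_at_radius",
    "radius_for_fov",
    "calibrate_model",
]

_VALIDATION_SAMPLES = 256


@dataclass(frozen=True)
class RadialPolynomialModel:
    """Radial polynomial camera model f(rho) = a0 + a2 rho^2 + ... + an rho^n.

    Parameters
    ----------
    coefficients
        ``(a0, a2, a3, ..., an)`` — the linear term is implicitly zero.
        ``a0`` must be positive. Degree n = len(coefficients).
    center
        Optical centre (cx, cy) in pixel coordinates of the host image.
    rho_max
        Largest valid radius in pixels (edge of the circular image field).

    Construction validates that the per-radius FOV is strictly increasing
    on [0, rho_max] (sampled at 256 radii); a model failing that check is
    not a physically meaningful lens.
    """

    coefficients: tuple[float, ...]
    center: tuple[float, float]
    rho_max: float

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if len(coeffs) < 1:
            raise DomainError("at least a0 is required")
        if not coeffs[0] > 0:
            raise DomainError(f"a0 must be positive, got {coeffs[0]}")
        if not self.rho_max > 0:
            raise DomainError(f"rho_max must be positive, got {self.rho_max}")
        rho = np.linspace(0.0, self.rho_max, _VALIDATION_SAMPLES)
        theta = np.arctan2(rho, self._f(rho))
        if np.any(np.diff(theta) <= 0):
            raise DomainError(
                "model is not FOV-monotone on [0, rho_max]; not a valid lens"
            )

    @property
    def degree(self) -> int:
        return len(self.coefficients)

    def _powers(self) -> np.ndarray:
        # exponent for each stored coefficient: a0 -> 0, a2 -> 2, a3 -> 3, ...
        return np.array([0] + list(range(2, self.degree + 1)))

    def _f(self, rho: np.ndarray | float) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        coeffs = np.asarray(self.coefficients)
        return (rho[..., None] ** self._powers() * coeffs).sum(axis=-1)

    def __call__(self, rho: float | np.ndarray) -> float | np.ndarray:
        """Evaluate f(rho)."""
        out = self._f(rho)
        return float(out) if np.isscalar(rho) else out

    @property
    def max_fov(self) -> float:
        """Full field of view at rho_max, degrees."""
        return fov_at_radius(self, self.rho_max)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        """JSON with the linear slot stored explicitly as 0."""
        a = self.coefficients
        stored = [a[0], 0.0, *a[1:]]
        return json.dumps(
            {
                "center": list(self.center),
                "rho_max": self.rho_max,
                "coefficients": stored,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RadialPolynomialModel":
        obj = json.loads(text)
        stored = obj["coefficients"]
        if len(stored) >= 2 and stored[1] != 0:
            raise DomainError("linear coefficient slot must be 0")
        coeffs = (stored[0], *stored[2:])
        return cls(
            coefficients=tuple(coeffs),
            center=tuple(obj["center"]),
            rho_max=float(obj["rho_max"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RadialPolynomialModel":
        return cls.from_json(Path(path).read_text())


def fov_at_radius(model: RadialPolynomialModel, rho: float) -> float:
    """Field of view subtended at radial distance ``rho``: 2*atan2(rho, f(rho)).

    Degrees; strictly increasing in rho for any valid model, 0 at the
    centre, and able to exceed 180 for lenses whose f(rho) turns negative.
    """
    if rho < 0 or rho > model.rho_max * (1 + 1e-12):
        raise DomainError(f"rho must be in [0, {model.rho_max}], got {rho}")
    return math.degrees(2.0 * math.atan2(rho, float(model._f(rho))))


def radius_for_fov(model: RadialPolynomialModel, fov_deg: float) -> float:
    """Radius at which the model's FOV equals ``fov_deg`` (degrees).

    The inverse of :func:`fov_at_radius`, found by bracketed root-finding
    (Brent) to 1e-9 * rho_max; well defined because FOV is strictly
    increasing on [0, rho_max].
    """
    if not fov_deg > 0:
        raise DomainError(f"FOV must be positive, got {fov_deg}")
    max_fov = model.max_fov
    if fov_deg > max_fov + 1e-9:
        raise FovNotReachableError(
            f"FOV {fov_deg} deg exceeds model maximum {max_fov:.3f} deg"
        )
    if fov_deg >= max_fov:
        return model.rho_max
    half = math.radians(fov_deg) / 2.0

    def g(rho: float) -> float:
        return math.atan2(rho, float(model._f(rho))) - half

    return brentq(g, 0.0, model.rho_max, xtol=1e-10 * model.rho_max)


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise DomainError("zero direction vector")
    return v / n


def project_direction(
    model: RadialPolynomialModel, direction: Sequence[float]
) -> tuple[float, float]:
    """Project a scene direction (camera frame, z along the axis) to (u, v).

    Solves for the unique rho >= 0 with atan2(rho, f(rho)) equal to the
    ray's angle from the optical axis, then scales the transverse direction
    to that radius. Returned (u, v) are pixels relative to the optical
    centre. Raises :class:`OutsideFieldError` when the ray's angle exceeds
    the model's half-FOV.
    """
    x, y, z = _unit(direction)
    r_t = math.hypot(x, y)
    if r_t == 0.0:
        if z <= 0:
            raise OutsideFieldError("backward axial direction")
        return 0.0, 0.0
    theta = math.atan2(r_t, z)  # angle from optical axis, [0, pi)
    max_half = math.radians(model.max_fov) / 2.0
    if theta > max_half + 1e-12:
        raise OutsideFieldError(
            f"direction at {math.degrees(theta):.3f} deg off axis exceeds "
            f"half-FOV {math.degrees(max_half):.3f} deg"
        )
    rho = radius_for_fov(model, math.degrees(2.0 * theta)) if theta > 0 else 0.0
    return rho * x / r_t, rho * y / r_t


def project_directions(
    model: RadialPolynomialModel, directions: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised projection of (N, 3) directions.

    Returns
    -------
    uv : (N, 2) array
        Image points relative to the optical centre (NaN where invisible).
    visible : (N,) bool array
        False for rays behind the camera or beyond the model's FOV.
    """
    d = np.asarray(directions, dtype=float)
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    d = np.divide(d, norms, out=np.zeros_like(d), where=norms > 0)
    r_t = np.hypot(d[:, 0], d[:, 1])
    theta = np.arctan2(r_t, d[:, 2])
    max_half = math.radians(model.max_fov) / 2.0
    visible = (norms[:, 0] > 0) & (theta <= max_half + 1e-12)
    uv = np.full((len(d), 2), np.nan)
    for i in np.nonzero(visible)[0]:
        if r_t[i] == 0.0:
            uv[i] = (0.0, 0.0)
        else:
            rho = radius_for_fov(model, math.degrees(2.0 * theta[i]))
            uv[i] = (rho * d[i, 0] / r_t[i], rho * d[i, 1] / r_t[i])
    return uv, visible


def back_project(
    model: RadialPolynomialModel, point: Sequence[float]
) -> np.ndarray:
    """Unit scene direction for image point (u, v) relative to the centre.

    The ray is proportional to (u, v, f(rho)) with rho = sqrt(u^2 + v^2).
    """
    u, v = float(point[0]), float(point[1])
    rho = math.hypot(u, v)
    if rho > model.rho_max * (1 + 1e-12):
        raise OutsideFieldError(
            f"point at rho={rho:.3f} outside image field (rho_max={model.rho_max})"
        )
    return _unit((u, v, float(model._f(rho))))


@dataclass(frozen=True)
class CorrespondenceSet:
    """Calibration correspondences: camera-frame 3D points vs image points.

    ``points_xyz`` is (N, 3) in the camera frame (z along the optical
    axis); ``pixels_uv`` is (N, 2) in pixels relative to the optical
    centre. Extrinsic pose resolution is assumed done upstream.
    """

    points_xyz: np.ndarray
    pixels_uv: np.ndarray

    def __post_init__(self) -> None:
        xyz = np.atleast_2d(np.asarray(self.points_xyz, dtype=float))
        uv = np.atleast_2d(np.asarray(self.pixels_uv, dtype=float))
        if xyz.shape[1] != 3 or uv.shape[1] != 2 or len(xyz) != len(uv):
            raise DomainError("expected (N,3) points and (N,2) pixels")
        object.__setattr__(self, "points_xyz", xyz)
        object.__setattr__(self, "pixels_uv", uv)

    def __len__(self) -> int:
        return len(self.points_xyz)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            np.hstack([self.points_xyz, self.pixels_uv]),
            columns=["X", "Y", "Z", "u", "v"],
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrespondenceSet":
        df = pd.read_csv(path)
        missing = {"X", "Y", "Z", "u", "v"} - set(df.columns)
        if missing:
            raise DomainError(f"correspondence CSV missing columns {missing}")
        return cls(df[["X", "Y", "Z"]].to_numpy(), df[["u", "v"]].to_numpy())


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted model plus the RMS residual of f(rho) against its targets."""

    model: RadialPolynomialModel
    rms_residual: float
    n_points: int


def calibrate_model(
    corr: CorrespondenceSet,
    degree: int = 4,
    center: tuple[float, float] = (0.0, 0.0),
    rho_max: float | None = None,
) -> CalibrationResult:
    """Fit polynomial coefficients from correspondences by linear least squares.

    For each pair with transverse 3D radius R_i = sqrt(X_i^2 + Y_i^2) > 0
    and image radius rho_i, collinearity of (u, v, f(rho)) with (X, Y, Z)
    requires f(rho_i) = Z_i * rho_i / R_i; the coefficients minimising the
    sum of squared deviations solve a linear system on the monomial basis
    {1, rho^2, rho^3, ..., rho^degree}. Points projecting to the exact
    centre carry no radial information and are dropped.

    Parameters
    ----------
    degree
        Highest polynomial power n (>= 2); the number of unknowns equals n.
    center, rho_max
        Stored on the returned model; ``rho_max`` defaults to the largest
        observed rho.
    """
    if degree < 2:
        raise DomainError(f"degree must be >= 2, got {degree}")
    xyz, uv = corr.points_xyz, corr.pixels_uv
    R = np.hypot(xyz[:, 0], xyz[:, 1])
    rho = np.hypot(uv[:, 0], uv[:, 1])
    keep = (R > 0) & (rho > 0)
    R, Z, rho = R[keep], xyz[keep, 2], rho[keep]
    n_unknowns = degree  # a0 plus a2..a_degree
    if len(rho) < n_unknowns:
        raise CalibrationError(
            f"{len(rho)} usable correspondences for {n_unknowns} unknowns"
        )
    if len(np.unique(np.round(rho, 6))) < 3:
        raise CalibrationError("correspondences span fewer than 3 distinct radii")
    powers = np.array([0] + list(range(2, degree + 1)))
    A = rho[:, None] ** powers[None, :]
    b = Z * rho / R
    coeffs, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < n_unknowns:
        raise CalibrationError("degenerate correspondences: rank-deficient fit")
    resid = A @ coeffs - b
    rms = float(np.sqrt(np.mean(resid**2)))
    model = RadialPolynomialModel(
        coefficients=tuple(coeffs),
        center=center,
        rho_max=float(rho_max) if rho_max is not None else float(rho.max()),
    )
    return CalibrationResult(model=model, rms_residual=rms, n_points=int(len(rho)))
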