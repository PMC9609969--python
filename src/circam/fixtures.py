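"""Synthetic fixtures: ground-truth lens models, checkerboard
correspondences, and deterministic demo images.

Real fisheye lenses ship without published polynomial coefficients, so
every model instance here is synthetic: a plausible ground-truth lens is
constructed analytically and used both as the calibration oracle (generate
correspondences from it, refit, compare) and as the camera for coverage
simulations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .distortion import CorrespondenceSet, RadialPolynomialModel, project_directions
from .errors import DomainError

__all__ = [
    "synthetic_fisheye_model",
    "BoardSpec",
    "BoardPose",
    "generate_checkerboard_correspondences",
    "generate_demo_image",
]

log = logging.getLogger(__name__)


def synthetic_fisheye_model(
    a0: float = 320.0,
    rho_max: float = 512.0,
    max_fov_deg: float = 185.0,
    center: tuple[float, float] = (512.0, 512.0),
) -> RadialPolynomialModel:
    """Synthetic wide-angle lens reaching ``max_fov_deg`` at ``rho_max``.

    A degree-2 radial polynomial f(rho) = a0 + a2*rho^2 with a2 chosen so
    that the FOV at rho_max equals the requested maximum (f goes slightly
    negative for beyond-hemisphere lenses). Stands in for a physical
    fisheye lens whose calibration coefficients are not available.
    """
    if not 0 < max_fov_deg < 360:
        raise DomainError("max_fov_deg must be in (0, 360)")
    half = math.radians(max_fov_deg) / 2.0
    f_end = rho_max / math.tan(half)  # negative beyond 180 deg
    a2 = (f_end - a0) / rho_max**2
    return RadialPolynomialModel(
        coefficients=(a0, a2), center=center, rho_max=rho_max
    )


@dataclass(frozen=True)
class BoardSpec:
    """Checkerboard phantom: inner-corner grid and square size (metres)."""

    rows: int = 6
    cols: int = 8
    square_size: float = 0.03

    def corners(self) -> np.ndarray:
        """(rows*cols, 3) board-frame corner points, z = 0, centred."""
        xs = (np.arange(self.cols) - (self.cols - 1) / 2.0) * self.square_size
        ys = (np.arange(self.rows) - (self.rows - 1) / 2.0) * self.square_size
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])


@dataclass(frozen=True)
class BoardPose:
    """Rigid transform board -> camera frame: Euler xyz degrees + translation."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.3)

    def matrix(self) -> tuple[np.ndarray, np.ndarray]:
        rx, ry, rz = (math.radians(a) for a in self.rotation_deg)

        def _rx(a):
            c, s = math.cos(a), math.sin(a)
            return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])

        def _ry(a):
            c, s = math.cos(a), math.sin(a)
            return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])

        def _rz(a):
            c, s = math.cos(a), math.sin(a)
            return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])

        return _rz(rz) @ _ry(ry) @ _rx(rx), np.asarray(self.translation, float)


def default_board_poses() -> list[BoardPose]:
    """A spread of frontal and tilted poses at varying depths."""
    return [
        BoardPose((0, 0, 0), (0.0, 0.0, 0.25)),
        BoardPose((15, 0, 0), (0.02, -0.01, 0.3)),
        BoardPose((-10, 20, 5), (-0.03, 0.02, 0.35)),
        BoardPose((20, -15, -10), (0.04, 0.03, 0.4)),
        BoardPose((-25, 10, 15), (-0.02, -0.04, 0.45)),
        BoardPose((5, 25, -5), (0.05, 0.0, 0.5)),
    ]


def generate_checkerboard_correspondences(
    gt_model: RadialPolynomialModel,
    board: BoardSpec | None = None,
    poses: list[BoardPose] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CorrespondenceSet:
    """Camera-frame corner points projected through a ground-truth model.

    Each pose transforms the board corners into the camera frame; corners
    are projected by ``gt_model`` and Gaussian pixel noise of standard
    deviation ``noise_sd`` is added. A pose placing any corner behind the
    camera or outside the FOV is rejected with a logged warning.
    Deterministic for a fixed seed.
    """
    board = board or BoardSpec()
    poses = poses if poses is not None else default_board_poses()
    rng = np.random.default_rng(seed)
    corners = board.corners()
    all_xyz, all_uv = [], []
    for k, pose in enumerate(poses):
        rot, t = pose.matrix()
        cam = corners @ rot.T + t
        if np.any(cam[:, 2] <= 0):
            log.warning("pose %d rejected: corners behind camera", k)
            continue
        uv, visible = project_directions(gt_model, cam)
        if not visible.all():
            log.warning("pose %d rejected: corners outside FOV", k)
            continue
        all_xyz.append(cam)
        all_uv.append(uv)
    if not all_xyz:
        return CorrespondenceSet(np.empty((0, 3)), np.empty((0, 2)))
    xyz = np.vstack(all_xyz)
    uv = np.vstack(all_uv)
    if noise_sd > 0:
        uv = uv + rng.normal(0.0, noise_sd, uv.shape)
    return CorrespondenceSet(xyz, uv)


def generate_demo_image(
    kind: str = "gradient",
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> np.ndarray:
    """Deterministic synthetic test image.

    ``gradient``: smooth two-axis ramp (good for interpolation null
    tests); ``checker``: 16-pixel checkerboard (makes barrel distortion
    visible); ``noise``: uniform 8-bit noise (incompressible, good for
    storage-gain demonstrations).
    """
    w, h = size
    if w < 16 or h < 16:
        raise DomainError(f"size must be at least 16x16, got {size}")
    if kind == "gradient":
        gx, gy = np.meshgrid(np.linspace(0, 1, w), np.linspace(0, 1, h))
        img = 255.0 * (0.5 * gx + 0.5 * gy)
    elif kind == "checker":
        gx, gy = np.meshgrid(np.arange(w) // 16, np.arange(h) // 16)
        img = 255.0 * ((gx + gy) % 2)
    elif kind == "noise":
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, size=(h, w)).astype(float)
    else:
        raise DomainError(f"unknown demo image kind {kind!r}")
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
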