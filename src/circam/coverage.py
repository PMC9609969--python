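"""Monte-Carlo comparison of circular vs rectangular capture domains.

A wearable camera photographs a dining table without aiming. Food items
are idealised as disks on the table plane; the camera is a radial
polynomial model worn at chest height, looking forward and down. For each
candidate field of view, the circular image domain is the FOV circle on
the sensor plane and the rectangular domain is the largest same-aspect
rectangle inscribed in it (the traditional crop). An item is *full* when
its entire boundary projects inside the domain, *missed* when none of it
does, *cut* otherwise; the loss fraction (cut + missed)/n quantifies the
food information lost. Because the rectangle is a subset of its circle,
rectangular loss dominates circular loss for every scene, and circular
loss is non-increasing in FOV (the domains are nested).

World frame: z up, table plane at z = table_z, camera above it looking
along +y tilted down by its pitch. Intrinsic rotation order yaw -> pitch
-> roll; positive pitch looks further down. All angles degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .distortion import RadialPolynomialModel, project_directions
from .errors import DegenerateGeometryError, DomainError, PackingError
from .geometry import AspectRatio, _eta
from .image_ops import CircularDomain, RectangularDomain

__all__ = [
    "FoodItem",
    "CameraPose",
    "SceneSpec",
    "SceneParams",
    "CoverageEntry",
    "CoverageReport",
    "uniform_disk",
    "generate_scene",
    "camera_rotation",
    "project_item",
    "classify_capture",
    "compare_domains",
    "monte_carlo_coverage",
    "optimal_pitch",
]


@dataclass(frozen=True)
class FoodItem:
    """Disk idealisation of a plate/bowl on the table plane (metres)."""

    center: tuple[float, float]
    radius: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise DomainError(f"item radius must be positive, got {self.radius}")

    def boundary_points(self, table_z: float, n: int) -> np.ndarray:
        """(n, 3) world points sampling the disk boundary."""
        phi = 2.0 * np.pi * np.arange(n) / n
        return np.column_stack(
            [
                self.center[0] + self.radius * np.cos(phi),
                self.center[1] + self.radius * np.sin(phi),
                np.full(n, table_z),
            ]
        )


@dataclass(frozen=True)
class CameraPose:
    """Camera position (m, world frame) and orientation (degrees)."""

    position: tuple[float, float, float]
    pitch_deg: float = 0.0
    roll_deg: float = 0.0
    yaw_deg: float = 0.0


@dataclass(frozen=True)
class SceneSpec:
    """Synthetic dining scene: table plane, food disks, camera pose."""

    table_z: float
    items: tuple[FoodItem, ...]
    camera: CameraPose

    def __post_init__(self) -> None:
        if self.camera.position[2] <= self.table_z:
            raise DegenerateGeometryError("camera must be above the table plane")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass(frozen=True)
class SceneParams:
    """Ranges for the scene generator (metres / degrees).

    Defaults describe plausible chest-worn dining geometry: the camera
    0.25-0.55 m above the table, food centred 0.25-0.6 m ahead, one to six
    items of radius 0.05-0.15 m scattered in a 0.5 m disk, and up to
    +/- 15 degrees of roll/yaw wear jitter. The pitch aims the optical
    axis at the scene-disk centre (the downward-looking rule).
    """

    camera_height: tuple[float, float] = (0.25, 0.55)
    food_distance: tuple[float, float] = (0.25, 0.6)
    n_items: tuple[int, int] = (1, 6)
    item_radius: tuple[float, float] = (0.05, 0.15)
    scene_disk_radius: float = 0.5
    tilt_jitter_deg: float = 15.0
    table_z: float = 0.0
    max_attempts: int = 10_000


def uniform_disk(
    rng: np.random.Generator,
    n: int,
    radius: float,
    center: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """n points uniform over a disk (inverse-CDF radius, uniform angle)."""
    r = radius * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    return np.column_stack(
        [center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)]
    )


def generate_scene(params: SceneParams, seed: int) -> SceneSpec:
    """Deterministic synthetic scene for a given seed.

    Items are placed uniformly in the scene disk, non-overlapping by
    rejection (at most ``params.max_attempts`` tries per item).
    """
    rng = np.random.default_rng(seed)
    h = rng.uniform(*params.camera_height)
    dist = rng.uniform(*params.food_distance)
    n_items = int(rng.integers(params.n_items[0], params.n_items[1] + 1))
    scene_center = (0.0, dist)
    items: list[FoodItem] = []
    for k in range(n_items):
        radius = rng.uniform(*params.item_radius)
        for _ in range(params.max_attempts):
            (xy,) = uniform_disk(rng, 1, params.scene_disk_radius, scene_center)
            if all(
                math.hypot(xy[0] - it.center[0], xy[1] - it.center[1])
                > radius + it.radius
                for it in items
            ):
                items.append(
                    FoodItem(center=(float(xy[0]), float(xy[1])), radius=radius,
                             label=f"item{k}")
                )
                break
        else:
            raise PackingError(
                f"cannot place item {k} within {params.max_attempts} attempts"
            )
    pitch = optimal_pitch(h, dist)
    j = params.tilt_jitter_deg
    pose = CameraPose(
        position=(0.0, 0.0, params.table_z + h),
        pitch_deg=pitch,
        roll_deg=float(rng.uniform(-j, j)),
        yaw_deg=float(rng.uniform(-j, j)),
    )
    return SceneSpec(table_z=params.table_z, items=tuple(items), camera=pose)


def camera_rotation(pose: CameraPose) -> np.ndarray:
    """World-from-camera rotation matrix.

    Camera frame: x right, y down (image convention), z along the optical
    axis. At zero pitch/roll/yaw the axis points along world +y; positive
    pitch tilts it down; intrinsic order yaw -> pitch -> roll.
    """
    yaw, pitch, roll = (
        math.radians(pose.yaw_deg),
        math.radians(pose.pitch_deg),
        math.radians(pose.roll_deg),
    )

    def rz(a: float) -> np.ndarray:
        c, s = math.cos(a), math.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def rx(a: float) -> np.ndarray:
        c, s = math.cos(a), math.sin(a)
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])

    base = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])
    return rz(yaw) @ base @ rx(-pitch) @ rz(roll)


def project_item(
    model: RadialPolynomialModel,
    pose: CameraPose,
    item: FoodItem,
    n_boundary: int = 64,
    table_z: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Project an item's boundary samples into the image.

    Returns ``(uv, visible)``: (n, 2) image points relative to the optical
    centre (NaN where invisible) and a boolean visibility mask; samples
    behind the camera or beyond the model FOV are flagged not visible.
    """
    if n_boundary < 8:
        raise DomainError(f"n_boundary must be >= 8, got {n_boundary}")
    if pose.position[2] <= table_z:
        raise DegenerateGeometryError("camera on or below the table plane")
    world = item.boundary_points(table_z, n_boundary)
    rot = camera_rotation(pose)
    cam = (world - np.asarray(pose.position)) @ rot  # rot.T applied row-wise
    behind = cam[:, 2] <= 0
    uv, visible = project_directions(model, cam)
    visible &= ~behind
    uv[~visible] = np.nan
    return uv, visible


def classify_capture(
    uv: np.ndarray,
    visible: np.ndarray,
    domain: CircularDomain | RectangularDomain,
) -> str:
    """Capture status of an item from its boundary samples.

    ``full`` iff every sample is visible and inside the domain; ``missed``
    iff no sample is inside; ``cut`` otherwise. Both domain kinds are
    convex, so a disk lies inside iff its boundary does.
    """
    if len(uv) == 0:
        raise DomainError("need at least one sample point")
    inside = np.zeros(len(uv), dtype=bool)
    if visible.any():
        pts = np.where(np.isnan(uv), np.inf, uv)
        inside = visible & domain.contains(pts)
    if inside.all() and visible.all():
        return "full"
    if not inside.any():
        return "missed"
    return "cut"


@dataclass(frozen=True)
class CoverageEntry:
    """Capture tallies for one (FOV, domain kind) combination."""

    fov_deg: float
    kind: str
    n_full: int
    n_cut: int
    n_missed: int
    loss: float
    mean_loss: float | None = None
    ci95_halfwidth: float | None = None


@dataclass(frozen=True)
class CoverageReport:
    """Coverage outcome over one scene (or aggregated over many draws)."""

    seed: int
    n_draws: int
    n_items: int
    entries: tuple[CoverageEntry, ...] = field(default_factory=tuple)

    def entry(self, fov_deg: float, kind: str) -> CoverageEntry:
        for e in self.entries:
            if e.fov_deg == fov_deg and e.kind == kind:
                return e
        raise KeyError((fov_deg, kind))

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def compare_domains(
    scene: SceneSpec,
    model: RadialPolynomialModel,
    fovs_deg: Sequence[float],
    aspect: AspectRatio | float = 4 / 3,
    n_boundary: int = 64,
    seed: int = 0,
) -> CoverageReport:
    """Classify every item under circular and inscribed rectangular domains.

    For each FOV, the circular domain radius comes from the model's
    per-radius FOV; the rectangular domain is the largest aspect-eta
    rectangle inscribed in that circle. Rectangular loss >= circular loss
    is guaranteed by set inclusion.
    """
    from .distortion import radius_for_fov

    eta = _eta(aspect)
    projections = [
        project_item(model, scene.camera, it, n_boundary, scene.table_z)
        for it in scene.items
    ]
    entries = []
    for fov in fovs_deg:
        radius = radius_for_fov(model, fov)
        circle = CircularDomain(center=(0.0, 0.0), radius=radius)
        rect = RectangularDomain.inscribed_in(circle, eta)
        for domain in (circle, rect):
            counts = {"full": 0, "cut": 0, "missed": 0}
            for uv, vis in projections:
                counts[classify_capture(uv, vis, domain)] += 1
            n = len(scene.items)
            loss = (counts["cut"] + counts["missed"]) / n if n else 0.0
            entries.append(
                CoverageEntry(
                    fov_deg=float(fov),
                    kind=domain.kind,
                    n_full=counts["full"],
                    n_cut=counts["cut"],
                    n_missed=counts["missed"],
                    loss=loss,
                )
            )
    return CoverageReport(
        seed=seed, n_draws=1, n_items=len(scene.items), entries=tuple(entries)
    )


def monte_carlo_coverage(
    params: SceneParams,
    model: RadialPolynomialModel,
    fovs_deg: Sequence[float],
    aspect: AspectRatio | float = 4 / 3,
    n_draws: int = 100,
    seed: int = 0,
    n_boundary: int = 64,
) -> CoverageReport:
    """Aggregate compare_domains over ``n_draws`` seeded scenes.

    Draw i uses seed ``seed + i``. Reports the per-(FOV, kind) mean loss
    with a normal-approximation 95% confidence half-width, plus summed
    capture counts; deterministic for a fixed base seed.
    """
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    losses: dict[tuple[float, str], list[float]] = {}
    counts: dict[tuple[float, str], np.ndarray] = {}
    total_items = 0
    for i in range(n_draws):
        scene = generate_scene(params, seed + i)
        total_items += len(scene.items)
        rep = compare_domains(scene, model, fovs_deg, aspect, n_boundary, seed + i)
        for e in rep.entries:
            key = (e.fov_deg, e.kind)
            losses.setdefault(key, []).append(e.loss)
            counts[key] = counts.get(key, np.zeros(3, dtype=int)) + np.array(
                [e.n_full, e.n_cut, e.n_missed]
            )
    entries = []
    for fov in fovs_deg:
        for kind in ("circular", "rectangular"):
            key = (float(fov), kind)
            ls = np.asarray(losses[key])
            mean = float(ls.mean())
            sd = float(ls.std(ddof=1)) if n_draws > 1 else 0.0
            half = 1.96 * sd / math.sqrt(n_draws)
            c = counts[key]
            entries.append(
                CoverageEntry(
                    fov_deg=float(fov),
                    kind=kind,
                    n_full=int(c[0]),
                    n_cut=int(c[1]),
                    n_missed=int(c[2]),
                    loss=mean,
                    mean_loss=mean,
                    ci95_halfwidth=float(half),
                )
            )
    return CoverageReport(
        seed=seed, n_draws=n_draws, n_items=total_items, entries=tuple(entries)
    )


def optimal_pitch(
    camera_height_above_table: float, horizontal_distance_to_food_center: float
) -> float:
    """Downward pitch (degrees) placing the food centroid on the optical axis.

    Simply atan(height / distance): the geometric rule behind orienting a
    chest-worn lens down toward the table.
    """
    h, d = camera_height_above_table, horizontal_distance_to_food_center
    if not (h > 0 and d > 0):
        raise DomainError("height and distance must be positive")
    return math.degrees(math.atan2(h, d))
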