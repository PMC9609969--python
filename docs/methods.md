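# Methods

## Scope and problem

A wearable dietary-assessment camera takes pictures at a fixed rate with
no aiming step. The round lens illuminates a circular image field (IF) on
the image plane; a conventional rectangular sensor readout crops that
circle, and an unaimed camera pays for the crop in missed or cut food
items. `circam` implements the design mathematics for circular-image
capture — closed-form sensor/lens geometry, a radial fisheye camera
model, the pixel-level operations circular images need, and a simulator
quantifying the capture-completeness advantage.

## Conventions

- Lengths are unit-free but must be consistent per call. Optical formats
  ("1/4 inch") are treated as literal diagonals; nominal format and die
  size differ on real chips, and reconciling datasheets is out of scope.
- Angles are **degrees at every public interface** (library, CLI, JSON);
  radians appear only inside computations.
- Screen ratio η = width/height. Pixel (i, j) has continuous centre
  (j + 0.5, i + 0.5), origin top-left, x right, y down. Positive rotation
  angles turn the displayed image counter-clockwise.
- Fill value for masked/out-of-field/rotated-in regions defaults to 0.

## Closed-form design geometry

For a circle of diameter d, the largest inscribed η-rectangle has its
diagonal on the circle diameter, covering 4η/(π(1+η²)) of the circle
area; `crop_waste_fraction` is its complement. It is symmetric under
η ↔ 1/η and minimal at η = 1 (one reason a 4:3 readout is preferable to
16:9 for circular capture). `effective_fov` splits a diagonal pinhole FOV
(2·atan(d/2f)) into per-axis FOVs through the width/diagonal and
height/diagonal ratios applied to the half-angle tangent.

The rematch calculus: to capture an IF of diameter d₁ on a chip of ratio
η, the chip height must equal d₁, giving minimum diagonal d₁√(1+η²);
`select_standard_format` then picks the smallest catalog format at least
that large (default catalog: 1/7″ … 1″, user-overridable). Pixel-density
planning offers two scenarios: `preserve_density` (σ₂ = σ₁, pixel count
ratio 1+η²) and `equal_count` (the circle holds exactly N₁ pixels,
σ₂ = σ₁√(4η/(π(1+η²))), ratio 4η/π). Reported percentages are rounded
half-up at the printed precision.

## Radial polynomial camera model

`RadialPolynomialModel` implements the omnidirectional mapping
f(ρ) = a₀ + a₂ρ² + a₃ρ³ + … + aₙρⁿ: the scene ray through the optical
centre and the 3D point (u, v, f(ρ)) lands at image point (u, v),
ρ = √(u²+v²). Design choices:

- **No linear term.** All powers 2…n are kept and only the linear term is
  fixed at zero, which keeps the mapping smooth at the centre; this is the
  standard omnidirectional-camera convention. Default degree n = 4.
- **Beyond-hemisphere lenses.** FOV(ρ) = 2·atan2(ρ, f(ρ)), so f(ρ) < 0 at
  large ρ gives FOVs above 180°. Construction rejects models whose FOV is
  not strictly increasing on [0, ρ_max] (sampled at 256 radii) — such a
  polynomial is not a physical lens.
- **Root finding.** Projection and `radius_for_fov` invert the strictly
  monotone ρ ↦ FOV(ρ) by bracketed Brent iteration to 1e-10·ρ_max;
  the axis direction maps to the exact centre. Bulk image resampling
  (undistortion) instead inverts a 4096-sample monotone table with linear
  interpolation — interpolation error there is orders of magnitude below
  a pixel.
- **Calibration** consumes camera-frame 3D points (extrinsic pose
  estimation is upstream and out of scope): collinearity gives
  f(ρᵢ) = Zᵢρᵢ/Rᵢ with Rᵢ = √(Xᵢ²+Yᵢ²), a linear least-squares problem on
  the basis {1, ρ², ρ³, …, ρⁿ} solved by SVD (`numpy.linalg.lstsq`).
  Points at the exact image centre carry no radial information and are
  dropped; fewer usable points than unknowns, fewer than three distinct
  radii, or a rank-deficient design matrix raise `CalibrationError`.
  The constant-polynomial limit is exactly the pinhole model, and the
  test suite pins FOV(ρ) = 2·atan(2ρ/2a₀) against the pinhole formula at
  1e-12 degrees.
- Model coefficients and ρ are in pixels; JSON serialization stores the
  linear slot explicitly as 0 for unambiguous round-tripping.

## Image operations

Masking sets pixels whose *centre* falls outside the circle to the fill
value (idempotent by construction). `storage_gain` reports the
compressed-size ratio masked/original (PNG reference codec; JPEG at
quality 90 by default) — constant corners compress to almost nothing.

Undistortion is an inverse mapping: each output pixel's radius is turned
into an incidence angle (stereographic θ = 2·atan(r/2F), rectilinear
θ = atan(r/F)), the angle into an input radius via the model's FOV table,
and the input sampled bilinearly (nearest-neighbour available for
pixel-exact tests). Angles beyond the model's half-FOV are filled. A
rectilinear output only ever requests θ < 90°, so a beyond-hemisphere
source needs no error path — the output simply covers the representable
cone. Sampling clamps coordinates and applies an explicit half-pixel
in-bounds mask, so border pixels survive floating-point jitter instead of
collapsing to fill.

Re-levelling rotates about the domain centre. A circular domain maps onto
itself: retention is exactly 1.0. A rectangular domain is cropped to the
largest *same-aspect* axis-aligned rectangle inscribed in the rotated
rectangle. With the same-aspect constraint the usual two-case critical-
angle analysis collapses to a single closed form: the inscribed rectangle
is a central scaling by k = 1/(cos α + max(η, 1/η)·sin α), retention k²
(centred is optimal because the container is centrally symmetric; corner
containment suffices by convexity). The test suite verifies this against
a polygon-containment brute force (shapely, binary search on k) to 1e-6
across a 1° grid.

## Coverage simulator

World frame: z up, table plane at z = 0, camera above it; at zero
pitch/roll/yaw the optical axis points along +y with camera-x right and
camera-y down; intrinsic rotation order yaw → pitch → roll, positive
pitch looking down. These conventions are stated because nothing forces
them; all results are invariant to the choice.

`generate_scene` draws camera height ~ U(0.25, 0.55) m, food-centre
distance ~ U(0.25, 0.6) m, 1–6 disk items of radius ~ U(0.05, 0.15) m
placed uniformly (non-overlapping, rejection capped at 10⁴ attempts per
item) in a 0.5 m disk, roll/yaw jitter ~ U(±15°), and the aiming pitch
atan(height/distance) — plausible chest-worn dining geometry chosen as
tool defaults, not measured values. Items are sampled at 64 boundary
points; both domain kinds are convex, so a disk is inside a domain iff
its boundary is. A sample behind the camera (z_cam ≤ 0) is flagged not
visible even for a beyond-hemisphere lens. Classification: *full* iff
every sample is visible and inside, *missed* iff none is inside, *cut*
otherwise; loss = (cut + missed)/n_items.

`compare_domains` pairs each circular FOV domain (radius from
`radius_for_fov`) with its inscribed η-rectangle, so rectangular loss ≥
circular loss pointwise (set inclusion) and circular loss is
non-increasing in FOV (nested domains) — the simulator's headline
properties, checked over 500 seeded scenes in the test suite.
`monte_carlo_coverage` derives per-draw seeds as base + index and reports
mean loss with a normal-approximation 95 % CI; identical parameters and
seed give bytewise-identical JSON reports.

`optimal_pitch` is the geometric aiming rule atan(height/distance); on a
symmetric one-item scene the simulated loss over a 1° pitch grid bottoms
out at that angle (ties allowed), which the suite checks.

## Synthetic fixtures

No physical lens coefficients are published for the fisheye lenses this
class of device uses, so every model instance is synthetic:
`synthetic_fisheye_model` builds a degree-2 polynomial hitting a chosen
maximum FOV (default 185° at ρ_max = 512 px, a₀ = 320 px) and serves as
ground truth for calibration (checkerboard corners posed in front of it,
projected, optionally noise-perturbed) and as the simulator's camera.
What passing tests show is therefore internal consistency and correct
mathematics under a realistic lens shape — not agreement with any
particular physical lens, nor with real dining imagery: the scene
generator idealises food as non-overlapping disks on an infinite table,
with no occlusion by hands, utensils, or the wearer's clothing, no
photometric effects, and no temporal picture-rate modelling.

## Problem sizes and determinism

Defaults keep everything desk-scale: 500-scene property sweeps, 10⁶-point
Monte-Carlo area cross-checks, 512×512 undistortion tests, 100-replicate
calibration bias checks. All stochastic code paths take a single integer
seed (`numpy.random.default_rng`); stochastic outputs embed their seed.

## Known limitations

- Unequal screen ratios before/after rematch are not modelled (the
  calculus assumes η unchanged; the formulas generalise but are not
  exposed).
- Tangential/decentering distortion, vignetting, chromatic aberration,
  and rolling shutter are out of scope; the model is purely radial.
- Calibration assumes camera-frame 3D points; joint intrinsic/extrinsic
  estimation and corner detection in real photographs are not provided.
- The coverage numbers are properties of the synthetic scene family, not
  field measurements.
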