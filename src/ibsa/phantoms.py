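"""Synthetic CT phantoms with analytically known surface areas.

Generates the fixtures that stand in for undistributed study data:
geometric solids (sphere, cube, cylinder, ellipsoid) and a composite
"body" (spheroid torso, neck cylinder, head sphere, leg cylinder — all
coaxial so every junction patch is a closed-form or exactly-integrable
surface of revolution), plus test-retest perturbation pairs and
synthetic height/weight cohorts.

Voxelization is by centre-sampling: a voxel is tissue iff its centre
lies inside the solid.  No partial-volume anti-aliasing is applied to
the phantom itself, so smoothing effects are attributable entirely to
the measurement pipeline under test.

Analytic truths: sphere 4πr²; cube 6a²; cylinder 2πr(r+h); ellipsoid by
the Thomsen approximation (p = 1.6075, max error ≈ 1.06%); composite by
summing part areas minus junction caps, with spheroid zones evaluated by
adaptive quadrature of the exact surface-of-revolution integrand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, ndimage

from .ct_io import CTVolume
from .errors import OutOfFieldError, PhantomOutOfBoundsError
from .formulas import Subject

THOMSEN_P = 1.6075


# ---------------------------------------------------------------------------
# Analytic surface areas
# ---------------------------------------------------------------------------

def sphere_area_mm2(r: float) -> float:
    return 4.0 * math.pi * r * r


def cube_area_mm2(a: float) -> float:
    return 6.0 * a * a


def cylinder_area_mm2(r: float, h: float) -> float:
    return 2.0 * math.pi * r * (r + h)


def ellipsoid_area_mm2(a: float, b: float, c: float, p: float = THOMSEN_P) -> float:
    """Thomsen approximation of the ellipsoid surface with semi-axes a, b, c."""
    ap, bp, cp = a**p, b**p, c**p
    return 4.0 * math.pi * ((ap * bp + ap * cp + bp * cp) / 3.0) ** (1.0 / p)


def _spheroid_zone_area(r_xy: float, r_z: float, rho_cut: float) -> float:
    """Area of the spheroid cap around the +z pole where sqrt(x²+y²) < rho_cut.

    Surface of revolution ρ(z) = r_xy·sqrt(1 − z²/r_z²); adaptive quadrature
    of the exact integrand 2π ρ √(1 + ρ'²) from z* to the pole.
    """
    if rho_cut >= r_xy:
        raise ValueError("zone cut radius must be smaller than the equatorial radius")
    z_star = r_z * math.sqrt(1.0 - (rho_cut / r_xy) ** 2)

    def integrand(z):
        u = 1.0 - z * z / (r_z * r_z)
        rho = r_xy * math.sqrt(max(u, 1e-300))
        drho = -r_xy * z / (r_z * r_z * math.sqrt(max(u, 1e-300)))
        return 2.0 * math.pi * rho * math.sqrt(1.0 + drho * drho)

    val, _ = integrate.quad(integrand, z_star, r_z, limit=400)
    return val


# ---------------------------------------------------------------------------
# Phantom specification and construction
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Declarative phantom description.

    dimensions (mm) per shape:
      sphere: radius; cube: edge; cylinder: radius, height;
      ellipsoid: semi_z, semi_y, semi_x;
      body_composite: torso_r_xy, torso_r_z, head_r, head_z, neck_r,
                      leg_r, leg_bottom_z (negative).
    """

    shape: str = "sphere"
    dimensions: dict = field(default_factory=lambda: {"radius": 50.0})
    spacing: tuple[float, float, float] | float = 1.0
    tissue_hu: float = 40.0
    air_hu: float = -1000.0
    cavities: list[dict] = field(default_factory=list)
    origin_offset_vox: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sd_hu: float = 0.0
    seed: int = 0
    margin_vox: int = 5
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if np.isscalar(self.spacing):
            self.spacing = (float(self.spacing),) * 3
        else:
            self.spacing = tuple(float(s) for s in self.spacing)
        for key, v in self.dimensions.items():
            if key == "leg_bottom_z":
                if v >= 0:
                    raise ValueError("leg_bottom_z must be negative")
            elif v <= 0:
                raise ValueError(f"dimension {key} must be positive")


@dataclass
class Phantom:
    """A generated phantom: calibrated CT, solid-mask oracle, analytic truth."""

    ct: CTVolume
    analytic_surface_cm2: float
    solid_mask: np.ndarray
    spec: PhantomSpec


def _solid_extent_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(lower, upper) physical bounds of the solid, (z, y, x) mm, centred frame."""
    d = spec.dimensions
    s = spec.shape
    if s == "sphere":
        r = d["radius"]
        lo, hi = [-r] * 3, [r] * 3
    elif s == "cube":
        a = d["edge"] / 2.0
        lo, hi = [-a] * 3, [a] * 3
    elif s == "cylinder":
        r, h = d["radius"], d["height"]
        lo, hi = [-h / 2, -r, -r], [h / 2, r, r]
    elif s == "ellipsoid":
        az, ay, ax = d["semi_z"], d["semi_y"], d["semi_x"]
        lo, hi = [-az, -ay, -ax], [az, ay, ax]
    elif s == "body_composite":
        rxy = max(d["torso_r_xy"], d["head_r"], d["leg_r"], d["neck_r"])
        lo = [d["leg_bottom_z"], -rxy, -rxy]
        hi = [d["head_z"] + d["head_r"], rxy, rxy]
    else:
        raise ValueError(f"unknown phantom shape {s!r}")
    return np.asarray(lo, float), np.asarray(hi, float)


def _inside(spec: PhantomSpec, z: np.ndarray, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    d = spec.dimensions
    s = spec.shape
    if s == "sphere":
        return z * z + y * y + x * x <= d["radius"] ** 2
    if s == "cube":
        a = d["edge"] / 2.0
        return (np.abs(z) <= a) & (np.abs(y) <= a) & (np.abs(x) <= a)
    if s == "cylinder":
        return (x * x + y * y <= d["radius"] ** 2) & (np.abs(z) <= d["height"] / 2.0)
    if s == "ellipsoid":
        return (z / d["semi_z"]) ** 2 + (y / d["semi_y"]) ** 2 \
            + (x / d["semi_x"]) ** 2 <= 1.0
    if s == "body_composite":
        rho2 = x * x + y * y
        torso = (z / d["torso_r_z"]) ** 2 + rho2 / d["torso_r_xy"] ** 2 <= 1.0
        head = (z - d["head_z"]) ** 2 + rho2 <= d["head_r"] ** 2
        neck = (rho2 <= d["neck_r"] ** 2) & (z >= 0) & (z <= d["head_z"])
        legs = (rho2 <= d["leg_r"] ** 2) & (z >= d["leg_bottom_z"]) & (z <= 0)
        return torso | head | neck | legs
    raise ValueError(f"unknown phantom shape {s!r}")


def analytic_surface_mm2(spec: PhantomSpec) -> float:
    """Exact (or Thomsen/quadrature) outer surface area of the solid, mm²."""
    d = spec.dimensions
    s = spec.shape
    if s == "sphere":
        return sphere_area_mm2(d["radius"])
    if s == "cube":
        return cube_area_mm2(d["edge"])
    if s == "cylinder":
        return cylinder_area_mm2(d["radius"], d["height"])
    if s == "ellipsoid":
        return ellipsoid_area_mm2(d["semi_z"], d["semi_y"], d["semi_x"])
    if s == "body_composite":
        rxy, rz = d["torso_r_xy"], d["torso_r_z"]
        rh, zh = d["head_r"], d["head_z"]
        rn, rl, zb = d["neck_r"], d["leg_r"], d["leg_bottom_z"]
        # torso minus the two junction zones
        area = ellipsoid_area_mm2(rz, rxy, rxy)
        area -= _spheroid_zone_area(rxy, rz, rn)   # neck enters the top pole
        area -= _spheroid_zone_area(rxy, rz, rl)   # legs enter the bottom pole
        # visible neck lateral: from torso exit to head entry
        z_torso_exit = rz * math.sqrt(1.0 - (rn / rxy) ** 2)
        z_head_entry = zh - math.sqrt(rh * rh - rn * rn)
        if z_head_entry <= z_torso_exit:
            raise ValueError("head overlaps torso; no visible neck")
        area += 2.0 * math.pi * rn * (z_head_entry - z_torso_exit)
        # head sphere minus the neck cap
        cap_h = rh - math.sqrt(rh * rh - rn * rn)
        area += sphere_area_mm2(rh) - 2.0 * math.pi * rh * cap_h
        # visible leg lateral + flat bottom disk
        z_leg_exit = -rz * math.sqrt(1.0 - (rl / rxy) ** 2)
        if zb >= z_leg_exit:
            raise ValueError("leg cylinder does not protrude below the torso")
        area += 2.0 * math.pi * rl * (z_leg_exit - zb) + math.pi * rl * rl
        return area
    raise ValueError(f"unknown phantom shape {s!r}")


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize the spec into a calibrated CT volume with seeded noise.

    The grid is sized to hold the solid with ``margin_vox`` voxels of air
    on every side (at least 3); ``grid_shape`` may pin the grid, in which
    case a solid that does not fit raises "phantom out of bounds".
    """
    spacing = np.asarray(spec.spacing, float)
    lo, hi = _solid_extent_mm(spec)
    mid = (lo + hi) / 2.0
    margin = max(int(spec.margin_vox), 3)
    offset_mm = np.asarray(spec.origin_offset_vox, float) * spacing
    if spec.grid_shape is not None:
        shape = tuple(int(n) for n in spec.grid_shape)
    else:
        n = np.ceil((hi - lo) / spacing).astype(int) + 2 * margin + 1
        shape = tuple(int(v) for v in n)
    half_extent = (np.asarray(shape) - 1) / 2.0 * spacing
    if np.any((hi - lo) / 2.0 + np.abs(offset_mm) > half_extent - 3 * spacing):
        raise PhantomOutOfBoundsError(
            "phantom out of bounds: solid does not fit the grid with a "
            "3-voxel air margin"
        )

    # grid centred on the solid's midpoint; the offset shifts the solid
    coords = [
        (np.arange(shape[a]) - (shape[a] - 1) / 2.0) * spacing[a]
        + mid[a] - offset_mm[a]
        for a in range(3)
    ]
    z = coords[0][:, None, None]
    y = coords[1][None, :, None]
    x = coords[2][None, None, :]

    solid = _inside(spec, z, y, x)
    vol = np.where(solid, spec.tissue_hu, spec.air_hu).astype(np.float32)
    for cav in spec.cavities:
        hu = float(cav.get("hu", spec.air_hu))
        cz, cy, cx = cav.get("center_mm", (0.0, 0.0, 0.0))
        if cav.get("shape", "sphere") == "sphere":
            r = float(cav["radius"])
            inside = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r * r
        else:
            az, ay, ax = cav["semi_axes"]
            inside = ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 \
                + ((x - cx) / ax) ** 2 <= 1.0
        vol[inside & solid] = hu
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        vol += rng.normal(0.0, spec.noise_sd_hu, size=vol.shape).astype(np.float32)

    ct = CTVolume(voxels=vol, spacing=tuple(spacing),
                  origin=(float(coords[0][0]), float(coords[1][0]),
                          float(coords[2][0])))
    return Phantom(
        ct=ct,
        analytic_surface_cm2=analytic_surface_mm2(spec) / 100.0,
        solid_mask=solid,
        spec=spec,
    )


def sphere_phantom(radius_mm: float = 50.0, spacing=1.0, **kw) -> Phantom:
    return make_phantom(PhantomSpec(shape="sphere",
                                    dimensions={"radius": radius_mm},
                                    spacing=spacing, **kw))


def cube_phantom(edge_mm: float = 50.0, spacing=1.0, **kw) -> Phantom:
    return make_phantom(PhantomSpec(shape="cube", dimensions={"edge": edge_mm},
                                    spacing=spacing, **kw))


def cylinder_phantom(radius_mm: float = 30.0, height_mm: float = 100.0,
                     spacing=1.0, **kw) -> Phantom:
    return make_phantom(PhantomSpec(
        shape="cylinder", dimensions={"radius": radius_mm, "height": height_mm},
        spacing=spacing, **kw))


def ellipsoid_phantom(semi_z_mm: float = 60.0, semi_y_mm: float = 50.0,
                      semi_x_mm: float = 40.0, spacing=1.0, **kw) -> Phantom:
    return make_phantom(PhantomSpec(
        shape="ellipsoid",
        dimensions={"semi_z": semi_z_mm, "semi_y": semi_y_mm, "semi_x": semi_x_mm},
        spacing=spacing, **kw))


def body_composite_phantom(spacing=1.5, **kw) -> Phantom:
    """Default composite body: spheroid torso, neck, head, coaxial legs."""
    dims = kw.pop("dimensions", {
        "torso_r_xy": 60.0, "torso_r_z": 90.0,
        "head_r": 35.0, "head_z": 150.0, "neck_r": 18.0,
        "leg_r": 35.0, "leg_bottom_z": -200.0,
    })
    return make_phantom(PhantomSpec(shape="body_composite", dimensions=dims,
                                    spacing=spacing, **kw))


# ---------------------------------------------------------------------------
# Test-retest acquisition pairs
# ---------------------------------------------------------------------------

def make_test_retest(ct: CTVolume, shift_vox=(0.0, 0.0, 0.0),
                     rotation_deg: float = 0.0, noise_sd_hu: float = 0.0,
                     seed: int = 0, air_hu: float = -1000.0) -> CTVolume:
    """Synthetic "retest" acquisition: rigid transform + fresh seeded noise.

    The rotation is about the z-axis through the volume centre in physical
    space; the shift is in voxel units; resampling is trilinear.
    """
    spacing = np.asarray(ct.spacing, float)
    theta = math.radians(rotation_deg)
    rot_phys = np.array([
        [1.0, 0.0, 0.0],
        [0.0, math.cos(theta), -math.sin(theta)],
        [0.0, math.sin(theta), math.cos(theta)],
    ])
    # voxel-space matrix: S^-1 R^-1 S  (physical rotation under anisotropy)
    s_mat = np.diag(spacing)
    mat = np.linalg.inv(s_mat) @ rot_phys.T @ s_mat
    centre = (np.asarray(ct.shape) - 1) / 2.0
    shift = np.asarray(shift_vox, float)
    offset = centre - mat @ centre - mat @ shift
    out = ndimage.affine_transform(ct.voxels, mat, offset=offset, order=1,
                                   mode="constant", cval=air_hu)
    border = np.zeros(ct.shape, dtype=bool)
    border[[0, -1], :, :] = border[:, [0, -1], :] = border[:, :, [0, -1]] = True
    if np.any(out[border] > air_hu + 500.0):
        raise OutOfFieldError("out of field: transform moved the body to the border")
    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd_hu, size=out.shape)
    return CTVolume(voxels=out.astype(np.float32), spacing=ct.spacing,
                    origin=ct.origin)


# ---------------------------------------------------------------------------
# Synthetic subject cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Correlated truncated-normal height/weight population.

    Defaults emulate an adult oncology population: H ~ N(1.70, 0.09²) m on
    [1.51, 1.92], W ~ N(75, 15²) kg on [42, 115], correlation 0.6.
    """

    height_mean_m: float = 1.70
    height_sd_m: float = 0.09
    height_bounds_m: tuple[float, float] = (1.51, 1.92)
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 15.0
    weight_bounds_kg: tuple[float, float] = (42.0, 115.0)
    correlation: float = 0.6


@dataclass
class SyntheticCohort:
    subjects: list[Subject]
    params: CohortParams
    seed: int


def make_cohort(n: int, seed: int = 0,
                params: CohortParams | None = None) -> SyntheticCohort:
    """Draw a deterministic correlated height/weight cohort by rejection."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    cov = np.array([
        [params.height_sd_m**2,
         params.correlation * params.height_sd_m * params.weight_sd_kg],
        [params.correlation * params.height_sd_m * params.weight_sd_kg,
         params.weight_sd_kg**2],
    ])
    mean = np.array([params.height_mean_m, params.weight_mean_kg])
    subjects: list[Subject] = []
    while len(subjects) < n:
        draws = rng.multivariate_normal(mean, cov, size=max(4 * n, 64),
                                        method="cholesky")
        for h, w in draws:
            if (params.height_bounds_m[0] <= h <= params.height_bounds_m[1]
                    and params.weight_bounds_kg[0] <= w <= params.weight_bounds_kg[1]):
                subjects.append(Subject(height_m=float(h), weight_kg=float(w),
                                        id=f"s{len(subjects):04d}"))
                if len(subjects) == n:
                    break
    return SyntheticCohort(subjects=subjects, params=params, seed=seed)
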