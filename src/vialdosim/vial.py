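"""Conical 1 mL reaction-vial geometry and uniform source sampling.

The vial is modelled as a full cone: apex at the origin, axis along +z,
heights in mm.  The default geometry has height 20 mm with the half-angle
chosen so the capacity is exactly 1 mL, i.e. tanθ = √(3·1000/(π·20³)) ≈
0.3455 (θ ≈ 19.1°).  The fill level for a volume V follows from
V = (π/3)·(h·tanθ)²·h.  The polyethylene wall (0.65 mm, 0.9 g/mL) and
the air above the fluid act as non-scoring absorbers: energy crossing
the fluid boundary counts as escaped, and backscatter is neglected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VialGeometry",
    "fill_level",
    "fill_height_mm",
    "sample_source",
    "distance_to_fluid_boundary",
    "inside_fluid",
]


@dataclass
class VialGeometry:
    """Full-cone vial, apex at origin, axis +z.

    ``cone_height_mm`` and ``capacity_uL`` fix the half-angle via
    V = (π/3)·h³·tan²θ (1 μL = 1 mm³ of water).
    """

    cone_height_mm: float = 20.0
    capacity_uL: float = 1000.0
    wall_thickness_mm: float = 0.65
    wall_density_g_per_mL: float = 0.9
    fluid_density_g_per_mL: float = 1.0
    tan_half_angle: float = field(init=False)

    def __post_init__(self) -> None:
        if self.cone_height_mm <= 0 or self.capacity_uL <= 0:
            raise ValueError("cone height and capacity must be positive")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall thickness must be positive")
        self.tan_half_angle = math.sqrt(
            3.0 * self.capacity_uL / (math.pi * self.cone_height_mm**3)
        )

    @property
    def half_angle_deg(self) -> float:
        return math.degrees(math.atan(self.tan_half_angle))

    def cone_volume_uL(self, height_mm: float) -> float:
        """Fluid volume enclosed below a surface at the given height."""
        return math.pi / 3.0 * (height_mm * self.tan_half_angle) ** 2 * height_mm

    def fluid_mass_g(self, volume_uL: float) -> float:
        return volume_uL * 1e-3 * self.fluid_density_g_per_mL


def fill_height_mm(geometry: VialGeometry, volume_uL: float) -> float:
    """Height of the fluid surface for a given fill volume (inverse of the
    cone-volume relation)."""
    if not 0.0 < volume_uL <= geometry.capacity_uL:
        raise ValueError(
            f"volume must be in (0, {geometry.capacity_uL}] uL, got {volume_uL}"
        )
    return (
        3.0 * volume_uL / (math.pi * geometry.tan_half_angle**2)
    ) ** (1.0 / 3.0)


# spec-facing alias
fill_level = fill_height_mm


def inside_fluid(
    geometry: VialGeometry, volume_uL: float, points: np.ndarray, atol: float = 1e-9
) -> np.ndarray:
    """Boolean mask: points (n,3) strictly inside the fluid cone."""
    p = np.atleast_2d(points)
    h = fill_height_mm(geometry, volume_uL)
    r2 = p[:, 0] ** 2 + p[:, 1] ** 2
    z = p[:, 2]
    return (z > -atol) & (z < h + atol) & (r2 <= (z * geometry.tan_half_angle) ** 2 + atol)


def sample_source(
    geometry: VialGeometry,
    volume_uL: float,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform source points in the fluid with isotropic directions.

    Sampling is by inverse CDF in cone coordinates: z ∝ z² (so
    z = h·u^{1/3}), radius ∝ r within the disc at z, azimuth uniform;
    directions uniform on the unit sphere.  Returns ``(positions,
    directions)`` as (n, 3) arrays; reproducible for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    h = fill_height_mm(geometry, volume_uL)
    z = h * rng.random(n) ** (1.0 / 3.0)
    r = z * geometry.tan_half_angle * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    mu = 2.0 * rng.random(n) - 1.0
    psi = 2.0 * np.pi * rng.random(n)
    s = np.sqrt(1.0 - mu**2)
    dirs = np.column_stack([s * np.cos(psi), s * np.sin(psi), mu])
    return pos, dirs


def distance_to_fluid_boundary(
    geometry: VialGeometry,
    volume_uL: float,
    points: np.ndarray,
    directions: np.ndarray,
) -> np.ndarray:
    """Exact ray distance from interior points to the fluid boundary.

    The boundary is the lateral cone surface x²+y² = (z·tanθ)² (with
    z ∈ [0, h]) plus the free-surface plane z = h.  Vectorized over
    (n, 3) point/direction arrays; raises if any point is outside the
    fluid.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    single = np.asarray(points).ndim == 1
    if not np.all(inside_fluid(geometry, volume_uL, p)):
        raise ValueError("all points must lie inside the fluid region")
    h = fill_height_mm(geometry, volume_uL)
    c2 = geometry.tan_half_angle**2
    big = np.inf

    # lateral surface: quadratic a t² + 2b t + c = 0
    a = d[:, 0] ** 2 + d[:, 1] ** 2 - c2 * d[:, 2] ** 2
    b = p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1] - c2 * p[:, 2] * d[:, 2]
    c = p[:, 0] ** 2 + p[:, 1] ** 2 - c2 * p[:, 2] ** 2

    t_cone = np.full(p.shape[0], big)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = b**2 - a * c
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
        for sign in (-1.0, 1.0):
            t = (-b + sign * sq) / a
            zhit = p[:, 2] + t * d[:, 2]
            ok = np.isfinite(t) & (t > 1e-12) & (zhit >= -1e-12) & (zhit <= h + 1e-12)
            t_cone = np.where(ok & (t < t_cone), t, t_cone)
        # linear case (ray parallel to the cone surface): a ≈ 0
        lin = np.abs(a) < 1e-14
        if np.any(lin):
            t = -c[lin] / (2.0 * b[lin])
            zhit = p[lin, 2] + t * d[lin, 2]
            ok = (t > 1e-12) & (zhit >= -1e-12) & (zhit <= h + 1e-12)
            t_cone[lin] = np.where(ok & (t < t_cone[lin]), t, t_cone[lin])

    # free surface z = h
    with np.errstate(divide="ignore", invalid="ignore"):
        t_top = (h - p[:, 2]) / d[:, 2]
    t_top = np.where((d[:, 2] > 0) & (t_top > 0), t_top, big)

    dist = np.minimum(t_cone, t_top)
    # a point numerically on the boundary heading outward gets distance 0
    dist = np.where(np.isfinite(dist), dist, 0.0)
    return dist[0] if single else dist
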