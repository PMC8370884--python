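"""Synthetic two-level phantoms: Derenzo-style disks, vessel trees, random disks.

All generators are pure functions of ``(grid, spec)``: with the same spec
(including its seed) they return bit-identical rasters. Rasterization uses a
pixel-centre-inside test with no anti-aliasing, so every phantom takes exactly
the value set ``{0, amplitude}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .geometry import ImageGrid, PressureImage

__all__ = [
    "PhantomSpec",
    "generate_derenzo",
    "generate_vessel_tree",
    "generate_random_disks",
    "generate_phantom",
    "EmptyPhantomError",
    "ResolutionWarning",
]


class EmptyPhantomError(ValueError):
    """Raised when a phantom spec rasterizes to zero foreground pixels."""


class ResolutionWarning(UserWarning):
    """Raised when phantom features are below the resolvable scale of the grid."""


#: Derenzo sector disk radii in mm, largest to smallest sector. The smallest
#: sits at the half-wavelength resolution limit of a 2.25 MHz transducer
#: (lambda/2 ~ 0.33 mm at 1500 m/s).
DERENZO_RADII = (1.6, 1.3, 1.05, 0.85, 0.65, 0.5)


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative description of a synthetic phantom.

    Parameters
    ----------
    family : str
        One of ``derenzo``, ``vessel``, ``disks``, ``custom``.
    amplitude : float
        Absorber level in Pa (background is 0). Default 1000 Pa (1 kPa).
    params : dict
        Family-specific geometry parameters; unspecified keys take the
        packaged defaults.
    rng_seed : int
        Seed for the stochastic families (``vessel``, ``disks``).
    """

    family: str
    amplitude: float = 1000.0
    params: dict[str, Any] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("derenzo", "vessel", "disks", "custom"):
            raise ValueError(f"unknown phantom family {self.family!r}")


# ---------------------------------------------------------------------------
# rasterization helpers


def _raster_disks(grid: ImageGrid, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Boolean (ny, nx) mask of the union of disks (pixel-centre-inside test)."""
    X, Y = grid.pixel_centers()
    mask = np.zeros(grid.shape, dtype=bool)
    for (cx, cy), r in zip(centers, radii):
        mask |= (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
    return mask


def _raster_capsules(grid: ImageGrid, segments: list[tuple[np.ndarray, np.ndarray, float]]) -> np.ndarray:
    """Union of thick line segments (capsules): dist(point, segment) <= radius."""
    X, Y = grid.pixel_centers()
    mask = np.zeros(grid.shape, dtype=bool)
    for p0, p1, r in segments:
        d = p1 - p0
        len2 = float(d @ d)
        px = X - p0[0]
        py = Y - p0[1]
        if len2 == 0.0:
            dist2 = px**2 + py**2
        else:
            t = np.clip((px * d[0] + py * d[1]) / len2, 0.0, 1.0)
            dist2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2
        mask |= dist2 <= r**2
    return mask


def _finish(grid: ImageGrid, mask: np.ndarray, amplitude: float) -> PressureImage:
    if amplitude != 0.0 and not mask.any():
        raise EmptyPhantomError("phantom spec produced zero foreground pixels")
    values = np.where(mask, float(amplitude), 0.0)
    return PressureImage(grid=grid, values=values, role="ground_truth")


# ---------------------------------------------------------------------------
# Derenzo


def _derenzo_layout(
    radii: tuple[float, ...],
    outer_radius: float,
    inner_margin: float,
    spacing_factor: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Disk centres/radii for a six-sector Derenzo arrangement.

    Each 60-degree sector holds disks of one radius on a triangular lattice
    with centre-to-centre spacing ``spacing_factor * 2r`` (default twice the
    diameter), every disk inside ``outer_radius``.
    """
    centers: list[tuple[float, float]] = []
    out_r: list[float] = []
    n_sector = len(radii)
    for k, r in enumerate(radii):
        theta = 2 * np.pi * k / n_sector + np.pi / n_sector  # sector bisector
        u = np.array([np.cos(theta), np.sin(theta)])  # axial (outward)
        v = np.array([-np.sin(theta), np.cos(theta)])  # lateral
        s = spacing_factor * 2 * r  # centre-to-centre spacing
        h = s * np.sqrt(3) / 2  # row pitch
        half_wedge = np.pi / n_sector
        row = 0
        while True:
            axial = inner_margin + 2 * r + row * h
            if axial + r > outer_radius:
                break
            for j in range(row + 1):
                lateral = (j - row / 2.0) * s
                c = axial * u + lateral * v
                dist = float(np.hypot(*c))
                if dist + r > outer_radius:
                    continue
                # keep the whole disk plus half an inter-sector gap inside the wedge
                ang_clear = np.arcsin(min(1.0, (r + 0.5 * r) / max(dist, 1e-9)))
                ang = np.arctan2(lateral, axial)
                if abs(ang) + ang_clear > half_wedge:
                    continue
                centers.append((c[0], c[1]))
                out_r.append(r)
            row += 1
    return np.array(centers), np.array(out_r)


def generate_derenzo(grid: ImageGrid, spec: PhantomSpec) -> PressureImage:
    """Rasterize a Derenzo-style resolution phantom.

    Six angular sectors hold disks of decreasing radius (default 1.2 down to
    0.3 mm) on triangular lattices, all inside a 9 mm circle. Two-level
    output: background 0, disks at ``spec.amplitude``.
    """
    if spec.family != "derenzo":
        raise ValueError(f"spec family {spec.family!r} is not 'derenzo'")
    p = spec.params
    radii = tuple(p.get("radii", DERENZO_RADII))
    outer_radius = float(p.get("outer_radius", 9.0))
    inner_margin = float(p.get("inner_margin", 1.2))
    spacing_factor = float(p.get("spacing_factor", 2.0))
    if spacing_factor < 1.0:
        raise ValueError("spacing_factor < 1 would overlap disks")

    centers, disk_r = _derenzo_layout(radii, outer_radius, inner_margin, spacing_factor)
    if min(radii) < 2 * grid.dx:
        warnings.warn(
            f"smallest disk radius {min(radii)} mm is below 2 px "
            f"({2 * grid.dx:.3f} mm); not resolvable on this grid",
            ResolutionWarning,
            stacklevel=2,
        )
    # validate: disks inside FOV and pairwise disjoint
    half_w = grid.extent[0] / 2
    if np.any(np.abs(centers).max(axis=1) + disk_r > half_w):
        raise ValueError("Derenzo spec places disks outside the field of view")
    d2 = np.sum((centers[:, None, :] - centers[None, :, :]) ** 2, axis=-1)
    rsum = disk_r[:, None] + disk_r[None, :]
    np.fill_diagonal(d2, np.inf)
    if np.any(d2 < rsum**2):
        raise ValueError("Derenzo spec produces overlapping disks")

    mask = _raster_disks(grid, centers, disk_r)
    return _finish(grid, mask, spec.amplitude)


# ---------------------------------------------------------------------------
# vessel tree


def _grow_tree(rng: np.random.Generator, p: dict[str, Any]) -> list[tuple[np.ndarray, np.ndarray, float]]:
    depth = int(p.get("depth", 5))
    root = np.asarray(p.get("root", (0.0, -8.0)), dtype=float)
    heading0 = float(p.get("heading", np.pi / 2))
    radius0 = float(p.get("radius", 0.45))
    length0 = float(p.get("length", 3.6))
    radius_decay = float(p.get("radius_decay", 0.75))
    length_decay = float(p.get("length_decay", 0.85))
    turn_lo = np.deg2rad(float(p.get("turn_min_deg", 15.0)))
    turn_hi = np.deg2rad(float(p.get("turn_max_deg", 40.0)))
    bound = float(p.get("bound", 9.3))  # keep vessels inside this radius

    segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    # stack of (start point, heading, radius, length, remaining depth)
    stack = [(root, heading0, radius0, length0, depth)]
    while stack:
        p0, heading, radius, length, d = stack.pop()
        # slight within-segment wiggle keeps branches curvilinear
        heading += rng.uniform(-0.1, 0.1)
        p1 = p0 + length * np.array([np.cos(heading), np.sin(heading)])
        p1 = np.clip(p1, -bound, bound)
        segments.append((p0, p1, radius))
        if d > 0:
            for sign in (+1.0, -1.0):
                turn = sign * rng.uniform(turn_lo, turn_hi)
                stack.append(
                    (p1, heading + turn, radius * radius_decay, length * length_decay, d - 1)
                )
    return segments


def generate_vessel_tree(grid: ImageGrid, spec: PhantomSpec) -> PressureImage:
    """Rasterize a procedural branching vessel phantom.

    A seeded recursive walk spawns two children per branch with the vessel
    radius decaying by 0.75 per generation and random turn angles of
    15-40 degrees, rasterized as thick polylines (capsules). Fully determined
    by ``(grid, spec)`` including ``spec.rng_seed``.
    """
    if spec.family != "vessel":
        raise ValueError(f"spec family {spec.family!r} is not 'vessel'")
    rng = np.random.default_rng(spec.rng_seed)
    segments = _grow_tree(rng, spec.params)
    mask = _raster_capsules(grid, segments)
    return _finish(grid, mask, spec.amplitude)


# ---------------------------------------------------------------------------
# random disks


def generate_random_disks(grid: ImageGrid, spec: PhantomSpec) -> PressureImage:
    """Random non-overlapping disks: a generic binary test phantom.

    Draws ``n_disks`` (default 3-6, seed-dependent) disks with radii in
    ``radius_range`` (default 1.2-2.8 mm) placed uniformly inside
    ``placement_radius`` (default 7 mm), rejecting overlaps.
    """
    if spec.family != "disks":
        raise ValueError(f"spec family {spec.family!r} is not 'disks'")
    p = spec.params
    rng = np.random.default_rng(spec.rng_seed)
    lo, hi = p.get("n_disks_range", (3, 6))
    n_disks = int(p.get("n_disks", rng.integers(lo, hi + 1)))
    r_lo, r_hi = p.get("radius_range", (1.2, 2.8))
    placement_radius = float(p.get("placement_radius", 7.0))
    gap = float(p.get("gap", 0.5))

    centers: list[np.ndarray] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < n_disks and attempts < 2000:
        attempts += 1
        r = rng.uniform(r_lo, r_hi)
        ang = rng.uniform(0, 2 * np.pi)
        rad = placement_radius * np.sqrt(rng.uniform())
        c = rad * np.array([np.cos(ang), np.sin(ang)])
        if np.hypot(*c) + r > placement_radius + 2.0:
            continue
        if any(np.hypot(*(c - c2)) < r + r2 + gap for c2, r2 in zip(centers, radii)):
            continue
        centers.append(c)
        radii.append(r)
    if not centers:
        raise EmptyPhantomError("could not place any disks with the given spec")
    mask = _raster_disks(grid, np.array(centers), np.array(radii))
    return _finish(grid, mask, spec.amplitude)


_GENERATORS = {
    "derenzo": generate_derenzo,
    "vessel": generate_vessel_tree,
    "disks": generate_random_disks,
}


def generate_phantom(grid: ImageGrid, spec: PhantomSpec) -> PressureImage:
    """Dispatch on ``spec.family``."""
    try:
        gen = _GENERATORS[spec.family]
    except KeyError:
        raise ValueError(f"no generator for phantom family {spec.family!r}") from None
    return gen(grid, spec)
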