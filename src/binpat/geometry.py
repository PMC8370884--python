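"""Imaging grids, detector rings, acquisition settings and pressure images.

Conventions used throughout the package:

* physical coordinates are in millimetres, with the origin at the centre of
  the field of view; pixel ``(iy, ix)`` of an ``ImageGrid`` has its centre at
  ``(x, y) = ((ix - (nx-1)/2) dx, (iy - (ny-1)/2) dx)``;
* image arrays are ``(ny, nx)`` and flatten in C order (row = y);
* the speed of sound is stored in m/s and converted to mm/us once, inside the
  forward-operator construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageGrid",
    "DetectorRing",
    "AcquisitionSettings",
    "PressureImage",
    "make_grid",
    "make_detector_ring",
    "GeometryWarning",
]


class GeometryWarning(UserWarning):
    """Raised for legal but suspicious geometry (e.g. detectors inside FOV)."""


@dataclass(frozen=True)
class ImageGrid:
    """A centred Cartesian pixel grid.

    Parameters
    ----------
    nx, ny : int
        Pixel counts along x and y (both >= 2).
    dx : float
        Isotropic pixel pitch in mm.
    """

    nx: int
    ny: int
    dx: float

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError(f"grid must be at least 2x2, got {self.nx}x{self.ny}")
        if not self.dx > 0:
            raise ValueError(f"pixel pitch must be positive, got {self.dx}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def extent(self) -> tuple[float, float]:
        """Physical size (width, height) of the FOV in mm."""
        return (self.nx * self.dx, self.ny * self.dx)

    @property
    def origin(self) -> tuple[float, float]:
        """Physical coordinate of pixel-centre (ix=0, iy=0) in mm."""
        return (-(self.nx - 1) / 2.0 * self.dx, -(self.ny - 1) / 2.0 * self.dx)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of shape (ny, nx) with pixel-centre coordinates."""
        x = (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.dx
        y = (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.dx
        return np.meshgrid(x, y)

    @property
    def half_diagonal(self) -> float:
        w, h = self.extent
        return float(np.hypot(w, h) / 2.0)


@dataclass(frozen=True)
class DetectorRing:
    """Point detectors on a circle about the grid centre.

    ``angles`` are strictly increasing, span less than 2*pi, and every
    detector sits at exactly ``radius`` (mm) from the FOV centre.
    """

    n_detectors: int
    radius: float
    angles: np.ndarray
    full_view: bool = True

    def __post_init__(self) -> None:
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", angles)
        if self.n_detectors < 1:
            raise ValueError("need at least one detector")
        if not self.radius > 0:
            raise ValueError("ring radius must be positive")
        if angles.shape != (self.n_detectors,):
            raise ValueError("angles length must equal n_detectors")
        if self.n_detectors > 1:
            if np.any(np.diff(angles) <= 0):
                raise ValueError("angles must be strictly increasing")
            if angles[-1] - angles[0] >= 2 * np.pi:
                raise ValueError("angles must span less than 2*pi")

    def positions(self) -> np.ndarray:
        """(n_detectors, 2) Cartesian detector coordinates in mm."""
        return self.radius * np.stack(
            [np.cos(self.angles), np.sin(self.angles)], axis=1
        )


@dataclass(frozen=True)
class AcquisitionSettings:
    """Time sampling of the acoustic traces.

    Attributes
    ----------
    c : float
        Speed of sound in m/s (assumed homogeneous).
    n_samples : int
        Time samples per detector trace.
    dt : float
        Sampling period in seconds.
    t0 : float
        Time of the first sample in seconds (0 = laser pulse).
    """

    c: float = 1500.0
    n_samples: int = 512
    dt: float = 50e-9
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("speed of sound must be positive")
        if self.n_samples < 1:
            raise ValueError("need at least one time sample")
        if not self.dt > 0:
            raise ValueError("sampling period must be positive")

    @property
    def c_mm_us(self) -> float:
        """Speed of sound in mm/us."""
        return self.c * 1e-3

    @property
    def f_nyquist(self) -> float:
        """Maximum resolvable frequency, Hz."""
        return 1.0 / (2.0 * self.dt)

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + self.dt * np.arange(self.n_samples)


@dataclass
class PressureImage:
    """A 2-D initial-pressure field on an :class:`ImageGrid`.

    ``role`` tags the image as ``ground_truth``, ``reconstruction`` or
    ``binary``; a binary image carries at most two distinct values.
    """

    grid: ImageGrid
    values: np.ndarray
    role: str = "reconstruction"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pressure image contains non-finite values")
        if self.role == "binary" and len(np.unique(self.values)) > 2:
            raise ValueError("binary image must take at most two distinct values")

    def ravel(self) -> np.ndarray:
        return self.values.ravel()

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.values)


def make_grid(nx: int, ny: int, dx: float) -> ImageGrid:
    """Create a centred imaging grid of ``nx`` x ``ny`` pixels at pitch ``dx`` mm.

    Examples
    --------
    A 402 x 402 grid at 0.05 mm pitch spans a 20.1 x 20.1 mm field of view.
    """
    return ImageGrid(nx=int(nx), ny=int(ny), dx=float(dx))


def make_detector_ring(
    n_detectors: int,
    radius: float,
    start_angle: float = 0.0,
    grid: ImageGrid | None = None,
) -> DetectorRing:
    """Equally spaced point detectors on a full ring of given radius (mm).

    Positions cover ``[start_angle, start_angle + 2*pi)``. If ``grid`` is
    given and the ring radius is smaller than the grid half-diagonal, a
    :class:`GeometryWarning` is emitted (detectors inside the imaged FOV).
    """
    if n_detectors < 1:
        raise ValueError("need at least one detector")
    if not radius > 0:
        raise ValueError("ring radius must be positive")
    if grid is not None and radius < grid.half_diagonal:
        warnings.warn(
            f"ring radius {radius} mm is inside the grid half-diagonal "
            f"{grid.half_diagonal:.2f} mm; detectors lie within the FOV",
            GeometryWarning,
            stacklevel=2,
        )
    angles = start_angle + 2 * np.pi * np.arange(n_detectors) / n_detectors
    return DetectorRing(
        n_detectors=int(n_detectors),
        radius=float(radius),
        angles=angles,
        full_view=True,
    )
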