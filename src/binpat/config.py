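"""Structured run configuration with schema validation.

A single YAML file drives the pipeline; unknown keys are rejected so typos
fail before any compute. All seeds are explicit (default 0) so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .binary import BinaryLevels
from .forward import NoiseSpec, TransducerModel
from .geometry import AcquisitionSettings, ImageGrid, make_detector_ring, make_grid
from .phantoms import PhantomSpec

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    nx: int = Field(ge=2)
    ny: int = Field(ge=2)
    dx: float = Field(gt=0, description="pixel pitch, mm")

    def build(self) -> ImageGrid:
        return make_grid(self.nx, self.ny, self.dx)


class RingConfig(_Strict):
    n_detectors: int = Field(default=80, ge=1)
    radius: float = Field(default=22.0, gt=0, description="mm")
    start_angle: float = 0.0

    def build(self):
        return make_detector_ring(self.n_detectors, self.radius, self.start_angle)


class AcquisitionConfig(_Strict):
    c: float = Field(default=1500.0, gt=0, description="m/s")
    n_samples: int = Field(default=512, ge=1)
    dt: float = Field(default=50e-9, gt=0, description="s")
    t0: float = 0.0

    def build(self) -> AcquisitionSettings:
        return AcquisitionSettings(c=self.c, n_samples=self.n_samples, dt=self.dt, t0=self.t0)


class TransducerConfig(_Strict):
    center_frequency: float = Field(default=2.25e6, gt=0, description="Hz")
    fractional_bandwidth: float = Field(default=0.7, gt=0, lt=2)
    stopband_rejection: float = Field(default=0.25, ge=0, lt=0.5)
    enabled: bool = True

    def build(self) -> TransducerModel | None:
        if not self.enabled:
            return None
        return TransducerModel(
            center_frequency=self.center_frequency,
            fractional_bandwidth=self.fractional_bandwidth,
            stopband_rejection=self.stopband_rejection,
        )


class PhantomConfig(_Strict):
    family: Literal["derenzo", "vessel", "disks", "custom"] = "derenzo"
    amplitude: float = 1000.0
    params: dict = Field(default_factory=dict)
    rng_seed: int = 0

    def build(self) -> PhantomSpec:
        return PhantomSpec(
            family=self.family,
            amplitude=self.amplitude,
            params=dict(self.params),
            rng_seed=self.rng_seed,
        )


class NoiseConfig(_Strict):
    snr_db: float | None = 30.0
    rng_seed: int = 0

    def build(self) -> NoiseSpec:
        return NoiseSpec(snr_db=self.snr_db, rng_seed=self.rng_seed)


class MethodConfig(_Strict):
    name: Literal["bp", "tikhonov", "l1", "binary"] = "binary"
    lam: float = Field(default=0.0, ge=0)
    max_iters: int = Field(default=300, ge=1)
    tol: float = Field(default=1e-6, gt=0)
    # binary-specific
    binary: dict = Field(default_factory=dict)
    levels: tuple[float, float] | None = None

    @model_validator(mode="after")
    def _check_levels(self):
        if self.levels is not None and not self.levels[0] < self.levels[1]:
            raise ValueError("levels must satisfy u0 < u1")
        return self

    def build_levels(self) -> BinaryLevels | None:
        return None if self.levels is None else BinaryLevels(*self.levels)


class RunConfig(_Strict):
    """Full pipeline configuration (defaults mirror the in-silico protocol)."""

    fine_grid: GridConfig = GridConfig(nx=201, ny=201, dx=0.1)
    recon_grid: GridConfig = GridConfig(nx=101, ny=101, dx=20.1 / 101)
    ring: RingConfig = RingConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    transducer: TransducerConfig = TransducerConfig()
    phantom: PhantomConfig = PhantomConfig()
    noise: NoiseConfig = NoiseConfig()
    method: MethodConfig = MethodConfig()
    output_dir: str = "."
    seed: int = 0


def load_config(path, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; ``overrides`` are dotted-key updates
    (CLI flags win over file keys)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key, value in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
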