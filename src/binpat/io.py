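"""Readers and writers: HDF5 sinograms, float TIFF images, PNG masks, CSV
tables and run manifests.

The sinogram container is an HDF5 file with dataset ``/sinogram``
(n_detectors x n_samples, float64) and attributes ``c_mps, dt_s, t0_s,
radius_mm, angles_rad, fc_hz, fbw, snr_db, seed`` carrying the full
acquisition geometry, so externally acquired data can be imported by writing
one file. Round-trips are bit-exact.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .evaluation import BinaryMask
from .forward import Sinogram, TransducerModel
from .geometry import AcquisitionSettings, DetectorRing, ImageGrid, PressureImage

__all__ = [
    "write_sinogram",
    "read_sinogram",
    "write_image",
    "read_image",
    "write_mask_png",
    "read_mask_png",
    "write_overlay_png",
    "write_trace_csv",
    "RunManifest",
]

_REQUIRED_ATTRS = ("c_mps", "dt_s", "t0_s", "radius_mm", "angles_rad")


def write_sinogram(
    path, sinogram: Sinogram, transducer: TransducerModel | None = None
) -> None:
    """Write a sinogram plus full acquisition metadata to HDF5."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("sinogram", data=sinogram.values, dtype="float64")
        ds.attrs["c_mps"] = sinogram.acquisition.c
        ds.attrs["dt_s"] = sinogram.acquisition.dt
        ds.attrs["t0_s"] = sinogram.acquisition.t0
        ds.attrs["radius_mm"] = sinogram.ring.radius
        ds.attrs["angles_rad"] = sinogram.ring.angles
        if transducer is not None:
            ds.attrs["fc_hz"] = transducer.center_frequency
            ds.attrs["fbw"] = transducer.fractional_bandwidth
            ds.attrs["stopband"] = transducer.stopband_rejection
        if sinogram.noise is not None:
            ds.attrs["snr_db"] = sinogram.noise["snr_db"]
            ds.attrs["seed"] = sinogram.noise["seed"]


def read_sinogram(path) -> tuple[Sinogram, TransducerModel | None]:
    """Read a sinogram container; raises listing any missing metadata."""
    with h5py.File(path, "r") as fh:
        if "sinogram" not in fh:
            raise KeyError(f"{path}: no /sinogram dataset")
        ds = fh["sinogram"]
        missing = [a for a in _REQUIRED_ATTRS if a not in ds.attrs]
        if missing:
            raise KeyError(
                f"{path}: sinogram metadata incomplete, missing attributes {missing}"
            )
        values = ds[()]
        angles = np.asarray(ds.attrs["angles_rad"], dtype=float)
        ring = DetectorRing(
            n_detectors=len(angles),
            radius=float(ds.attrs["radius_mm"]),
            angles=angles,
        )
        acq = AcquisitionSettings(
            c=float(ds.attrs["c_mps"]),
            n_samples=values.shape[1],
            dt=float(ds.attrs["dt_s"]),
            t0=float(ds.attrs["t0_s"]),
        )
        noise = None
        if "snr_db" in ds.attrs:
            noise = {"snr_db": float(ds.attrs["snr_db"]), "seed": int(ds.attrs["seed"])}
        transducer = None
        if "fc_hz" in ds.attrs:
            transducer = TransducerModel(
                center_frequency=float(ds.attrs["fc_hz"]),
                fractional_bandwidth=float(ds.attrs["fbw"]),
                stopband_rejection=float(ds.attrs.get("stopband", 0.0)),
            )
    return Sinogram(values=values, ring=ring, acquisition=acq, noise=noise), transducer


def write_image(path, image: PressureImage) -> None:
    """Write an image as single-channel 32-bit float TIFF; the pixel pitch is
    stored in the TIFF resolution tag (pixels per cm)."""
    px_per_cm = 10.0 / image.grid.dx
    tifffile.imwrite(
        path,
        image.values.astype(np.float32),
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )


def read_image(path, role: str = "reconstruction") -> PressureImage:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        res = page.tags.get("XResolution")
        if res is not None:
            num, den = res.value
            dx = 10.0 * den / num  # pixels/cm -> mm pitch
        else:
            dx = 1.0
    ny, nx = values.shape
    return PressureImage(grid=ImageGrid(nx=nx, ny=ny, dx=dx), values=values, role=role)


def write_mask_png(path, mask: BinaryMask) -> None:
    """8-bit PNG, foreground 255."""
    import imageio.v3 as iio

    iio.imwrite(path, (mask.values * 255).astype(np.uint8), extension=".png")


def read_mask_png(path) -> BinaryMask:
    import imageio.v3 as iio

    arr = iio.imread(path)
    return BinaryMask(values=(np.asarray(arr) > 127), provenance="file")


def write_overlay_png(path, rgb: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, rgb.astype(np.uint8), extension=".png")


def write_trace_csv(path, trace, column: str = "objective") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", column])
        for k, val in enumerate(np.asarray(trace).ravel()):
            writer.writerow([k, repr(float(val))])


def write_system_matrix(path, A) -> None:
    """Cache a built operator to HDF5 (CSR triplets + geometry attributes)."""
    G = A.G
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=G.data)
        fh.create_dataset("indices", data=G.indices)
        fh.create_dataset("indptr", data=G.indptr)
        fh.attrs["shape"] = G.shape
        fh.attrs["grid"] = (A.grid.nx, A.grid.ny, A.grid.dx)
        fh.attrs["c_mps"] = A.acquisition.c
        fh.attrs["dt_s"] = A.acquisition.dt
        fh.attrs["t0_s"] = A.acquisition.t0
        fh.attrs["n_samples"] = A.acquisition.n_samples
        fh.attrs["radius_mm"] = A.ring.radius
        fh.attrs["angles_rad"] = A.ring.angles
        if A.transducer is not None:
            fh.attrs["fc_hz"] = A.transducer.center_frequency
            fh.attrs["fbw"] = A.transducer.fractional_bandwidth
            fh.attrs["stopband"] = A.transducer.stopband_rejection


def read_system_matrix(path):
    """Load a cached operator written by :func:`write_system_matrix`."""
    import scipy.sparse as sp

    from .forward import SystemMatrix

    with h5py.File(path, "r") as fh:
        G = sp.csr_matrix(
            (fh["data"][()], fh["indices"][()], fh["indptr"][()]),
            shape=tuple(fh.attrs["shape"]),
        )
        nx, ny, dx = fh.attrs["grid"]
        grid = ImageGrid(nx=int(nx), ny=int(ny), dx=float(dx))
        angles = np.asarray(fh.attrs["angles_rad"], dtype=float)
        ring = DetectorRing(
            n_detectors=len(angles), radius=float(fh.attrs["radius_mm"]), angles=angles
        )
        acq = AcquisitionSettings(
            c=float(fh.attrs["c_mps"]),
            n_samples=int(fh.attrs["n_samples"]),
            dt=float(fh.attrs["dt_s"]),
            t0=float(fh.attrs["t0_s"]),
        )
        transducer = None
        if "fc_hz" in fh.attrs:
            transducer = TransducerModel(
                center_frequency=float(fh.attrs["fc_hz"]),
                fractional_bandwidth=float(fh.attrs["fbw"]),
                stopband_rejection=float(fh.attrs.get("stopband", 0.0)),
            )
    return SystemMatrix(G, grid, ring, acq, transducer)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Inventory of a pipeline run: config hash, package version, outputs."""

    config_hash: str
    package_version: str
    files: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def add(self, path) -> None:
        p = Path(path)
        self.files[p.name] = _sha256(p)

    def write(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "config_hash": self.config_hash,
                    "package_version": self.package_version,
                    "files": self.files,
                },
                fh,
                sort_keys=True,
            )
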