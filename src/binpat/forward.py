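"""Discretized acoustic forward model for 2-D photoacoustic tomography.

The forward operator maps an initial-pressure image ``x`` to detector time
traces ``b`` through ``A x = b``. Each row of ``A`` is a discretized
circular-mean (circular Radon) projection: the trace sample of detector ``d``
at time ``t_k`` collects, with bilinear temporal splitting and 1/r spherical
spreading, the pixels lying at distance ``c * t_k`` from that detector. A
bandlimited transducer is modelled as a zero-phase Gaussian band-pass applied
along the time axis and folded into the operator, so the forward/adjoint pair
stays exactly self-consistent (the frequency response is real and symmetric,
hence the filter is self-adjoint).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import LinearOperator

from ._linalg import power_iteration
from .geometry import AcquisitionSettings, DetectorRing, ImageGrid, PressureImage

__all__ = [
    "TransducerModel",
    "Sinogram",
    "NoiseSpec",
    "SystemMatrix",
    "build_system_matrix",
    "forward",
    "apply_transducer_response",
    "add_awgn",
    "simulate_measurement",
    "CoverageError",
    "AliasingError",
    "UndefinedSNRError",
    "InverseCrimeWarning",
]


class CoverageError(ValueError):
    """The time window does not cover the field of view from every detector."""


class AliasingError(ValueError):
    """Transducer passband exceeds the Nyquist frequency of the sampling."""


class UndefinedSNRError(ValueError):
    """SNR calibration requested on an all-zero signal."""


class InverseCrimeWarning(UserWarning):
    """Forward and inversion grids are identical (inverse crime)."""


@dataclass(frozen=True)
class TransducerModel:
    """Bandlimited transducer: Gaussian amplitude response, zero phase.

    ``center_frequency`` (Hz) and ``fractional_bandwidth`` define the -6 dB
    band edges ``fc * (1 -/+ bw/2)``; e.g. 2.25 MHz at 70% bandwidth detects
    up to 3.0375 MHz. The DC component is removed exactly.

    ``stopband_rejection`` is the finite low-frequency rejection floor of the
    element (amplitude units; default 0.25, i.e. -12 dB): below the centre
    frequency the response never falls under this floor. An idealized
    Gaussian would leave blob-like absorbers with rim-only signatures that no
    linear reconstruction could refill; real transducers leak low-frequency
    energy at a finite stop-band level. Set it to 0 for the pure Gaussian.
    """

    center_frequency: float = 2.25e6
    fractional_bandwidth: float = 0.7
    stopband_rejection: float = 0.25

    def __post_init__(self) -> None:
        if not self.center_frequency > 0:
            raise ValueError("center frequency must be positive")
        if not 0 < self.fractional_bandwidth < 2:
            raise ValueError("fractional bandwidth must be in (0, 2)")
        if not 0 <= self.stopband_rejection < 0.5:
            raise ValueError("stop-band rejection floor must be in [0, 0.5)")

    @property
    def f_min(self) -> float:
        """Lower -6 dB band edge, Hz."""
        return self.center_frequency * (1 - self.fractional_bandwidth / 2)

    @property
    def f_max(self) -> float:
        """Upper -6 dB band edge (maximum detectable frequency), Hz."""
        return self.center_frequency * (1 + self.fractional_bandwidth / 2)

    def amplitude_response(self, freqs: np.ndarray) -> np.ndarray:
        """Gaussian response: 1 at fc, 1/2 (-6 dB) at the band edges, floored
        at ``stopband_rejection`` below fc, exactly 0 at DC."""
        half_width = self.center_frequency * self.fractional_bandwidth / 2
        sigma = half_width / np.sqrt(2 * np.log(2))
        resp = np.exp(-((np.abs(freqs) - self.center_frequency) ** 2) / (2 * sigma**2))
        if self.stopband_rejection > 0:
            resp = np.where(
                np.abs(freqs) < self.center_frequency,
                np.maximum(resp, self.stopband_rejection),
                resp,
            )
        return np.where(freqs == 0.0, 0.0, resp)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise calibrated to a data SNR in dB.

    ``snr_db = None`` means clean (no noise). The realised noise is a pure
    function of ``rng_seed``.
    """

    snr_db: float | None
    rng_seed: int = 0

    @property
    def clean(self) -> bool:
        return self.snr_db is None or np.isinf(self.snr_db)


@dataclass
class Sinogram:
    """Detector time-series data ``b`` with acquisition metadata.

    ``values`` is ``(n_detectors, n_samples)``; flattening in C order gives
    the detector-major, time-minor vector matching the system-matrix rows.
    ``noise`` records ``{"snr_db": float, "seed": int}`` or None when clean.
    """

    values: np.ndarray
    ring: DetectorRing
    acquisition: AcquisitionSettings
    noise: dict | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.ring.n_detectors, self.acquisition.n_samples)
        if self.values.shape != expected:
            raise ValueError(f"sinogram shape {self.values.shape} != {expected}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")

    def ravel(self) -> np.ndarray:
        return self.values.ravel()


def _bandpass_traces(values: np.ndarray, transducer: TransducerModel, dt: float) -> np.ndarray:
    """Zero-phase band-pass of each (row) trace via the real FFT."""
    n = values.shape[-1]
    freqs = np.fft.rfftfreq(n, d=dt)
    H = transducer.amplitude_response(freqs)
    return np.fft.irfft(np.fft.rfft(values, axis=-1) * H, n=n, axis=-1)


class SystemMatrix:
    """Sparse circular-Radon operator, optionally composed with a transducer.

    ``shape`` is ``(NM, NP)`` with ``NM = n_detectors * n_samples`` and
    ``NP = nx * ny``. ``forward``/``adjoint`` apply ``A`` and ``A^T``; with a
    transducer, ``A = F G`` where ``G`` is the geometric sparse matrix and
    ``F`` the (self-adjoint) band-pass, so ``A^T = G^T F``.
    """

    def __init__(
        self,
        geometric: sp.csr_matrix,
        grid: ImageGrid,
        ring: DetectorRing,
        acquisition: AcquisitionSettings,
        transducer: TransducerModel | None = None,
    ) -> None:
        self.G = geometric
        self.grid = grid
        self.ring = ring
        self.acquisition = acquisition
        self.transducer = transducer
        self._GT = geometric.T.tocsr()
        self._lipschitz: float | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.G.shape

    @property
    def n_rows(self) -> int:
        return self.G.shape[0]

    @property
    def n_cols(self) -> int:
        return self.G.shape[1]

    def _filter(self, y: np.ndarray) -> np.ndarray:
        if self.transducer is None:
            return y
        traces = y.reshape(self.ring.n_detectors, self.acquisition.n_samples)
        return _bandpass_traces(traces, self.transducer, self.acquisition.dt).ravel()

    def matvec(self, x: np.ndarray) -> np.ndarray:
        return self._filter(self.G @ np.asarray(x, dtype=float).ravel())

    def rmatvec(self, y: np.ndarray) -> np.ndarray:
        return self._GT @ self._filter(np.asarray(y, dtype=float).ravel())

    def forward(self, image: PressureImage) -> Sinogram:
        """Apply the operator to an image on the matching grid."""
        if image.grid != self.grid:
            raise ValueError(
                f"image grid {image.grid.shape} does not match operator grid "
                f"{self.grid.shape}"
            )
        b = self.matvec(image.ravel())
        return Sinogram(
            values=b.reshape(self.ring.n_detectors, self.acquisition.n_samples),
            ring=self.ring,
            acquisition=self.acquisition,
        )

    def adjoint(self, sinogram: Sinogram) -> np.ndarray:
        """Apply A^T to a sinogram; returns the (ny, nx) image array."""
        if sinogram.values.shape != (self.ring.n_detectors, self.acquisition.n_samples):
            raise ValueError("sinogram shape does not match operator")
        return self.rmatvec(sinogram.ravel()).reshape(self.grid.shape)

    def as_linear_operator(self) -> LinearOperator:
        return LinearOperator(self.shape, matvec=self.matvec, rmatvec=self.rmatvec)

    def norm_squared(self) -> float:
        """Cached power-iteration estimate of ||A||_2^2 (largest eig of A^T A)."""
        if self._lipschitz is None:
            self._lipschitz = power_iteration(
                self.matvec, self.rmatvec, self.n_cols, iters=20, seed=0
            )
        return self._lipschitz


def build_system_matrix(
    grid: ImageGrid,
    ring: DetectorRing,
    acquisition: AcquisitionSettings,
    transducer: TransducerModel | None = None,
) -> SystemMatrix:
    """Discretize the circular-mean projection onto the time samples.

    For detector ``d`` and pixel ``p`` at distance ``r`` the arrival time
    ``r/c`` is split bilinearly between the two adjacent time bins; the
    weight carries the pixel-area to arc-length conversion and the 1/(2 pi r)
    spherical spreading of a 2-D circular mean. Rows are detector-major.

    Raises
    ------
    CoverageError
        If the time window ends before the farthest pixel's arrival.
    AliasingError
        If the transducer passband exceeds Nyquist.
    """
    c = acquisition.c_mm_us
    dt_us = acquisition.dt * 1e6
    t0_us = acquisition.t0 * 1e6
    n_t = acquisition.n_samples
    if transducer is not None and transducer.f_max > acquisition.f_nyquist:
        raise AliasingError(
            f"transducer f_max {transducer.f_max:.4g} Hz exceeds Nyquist "
            f"{acquisition.f_nyquist:.4g} Hz"
        )

    X, Y = grid.pixel_centers()
    px = X.ravel()
    py = Y.ravel()
    n_p = grid.n_pixels
    positions = ring.positions()

    t_end = t0_us + (n_t - 1) * dt_us
    max_dist = float(np.max(np.hypot(*positions.T))) + grid.half_diagonal
    if c * t_end < max_dist:
        raise CoverageError(
            f"time window covers {c * t_end:.2f} mm but FOV requires "
            f"{max_dist:.2f} mm from the farthest detector"
        )

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    col_idx = np.arange(n_p, dtype=np.int64)
    for d, (dx_pos, dy_pos) in enumerate(positions):
        r = np.hypot(px - dx_pos, py - dy_pos)
        s = (r / c - t0_us) / dt_us
        i0 = np.floor(s).astype(np.int64)
        frac = s - i0
        w = grid.dx**2 / (2 * np.pi * np.maximum(r, grid.dx / 2) * c * dt_us)
        base = d * n_t
        for ii, ww in ((i0, (1 - frac) * w), (i0 + 1, frac * w)):
            valid = (ii >= 0) & (ii < n_t) & (ww > 0)
            rows.append(base + ii[valid])
            cols.append(col_idx[valid])
            vals.append(ww[valid])

    G = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ring.n_detectors * n_t, n_p),
    ).tocsr()
    return SystemMatrix(G, grid, ring, acquisition, transducer)


def forward(A: SystemMatrix, image: PressureImage) -> Sinogram:
    """Simulate the sinogram ``b = A x`` (linear in the image)."""
    return A.forward(image)


def apply_transducer_response(sinogram: Sinogram, transducer: TransducerModel) -> Sinogram:
    """Filter every trace with the zero-phase Gaussian band-pass.

    The -6 dB edges sit at ``fc * (1 -/+ bw/2)`` and the DC component is
    removed exactly.
    """
    if transducer.f_max > sinogram.acquisition.f_nyquist:
        raise AliasingError(
            f"transducer f_max {transducer.f_max:.4g} Hz exceeds Nyquist "
            f"{sinogram.acquisition.f_nyquist:.4g} Hz"
        )
    filtered = _bandpass_traces(sinogram.values, transducer, sinogram.acquisition.dt)
    return Sinogram(
        values=filtered,
        ring=sinogram.ring,
        acquisition=sinogram.acquisition,
        noise=sinogram.noise,
    )


def add_awgn(sinogram: Sinogram, noise_spec: NoiseSpec) -> Sinogram:
    """Add white Gaussian noise at the requested data SNR.

    The SNR is defined globally on the whole sinogram in amplitude-ratio
    decibels: ``sigma = rms(signal) / 10^(snr_db/20)``.
    """
    if noise_spec.clean:
        return Sinogram(
            values=sinogram.values.copy(),
            ring=sinogram.ring,
            acquisition=sinogram.acquisition,
            noise=None,
        )
    rms = float(np.sqrt(np.mean(sinogram.values**2)))
    if rms == 0.0:
        raise UndefinedSNRError("cannot calibrate SNR on an all-zero sinogram")
    sigma = rms / 10 ** (noise_spec.snr_db / 20)
    rng = np.random.default_rng(noise_spec.rng_seed)
    noisy = sinogram.values + rng.normal(0.0, sigma, size=sinogram.values.shape)
    return Sinogram(
        values=noisy,
        ring=sinogram.ring,
        acquisition=sinogram.acquisition,
        noise={"snr_db": float(noise_spec.snr_db), "seed": int(noise_spec.rng_seed)},
    )


def simulate_measurement(
    phantom_fine: PressureImage,
    ring: DetectorRing,
    acquisition: AcquisitionSettings,
    transducer: TransducerModel | None,
    noise_spec: NoiseSpec,
    recon_grid: ImageGrid,
) -> tuple[Sinogram, SystemMatrix]:
    """Simulate data on a fine grid and return the coarse inversion operator.

    The sinogram is produced by the fine-grid operator built from
    ``phantom_fine.grid``; the returned :class:`SystemMatrix` is built on
    ``recon_grid``. Using a finer forward grid than the inversion grid avoids
    the inverse crime; identical grids are allowed but flagged with
    :class:`InverseCrimeWarning`.
    """
    if phantom_fine.grid == recon_grid:
        warnings.warn(
            "forward and reconstruction grids are identical (inverse crime)",
            InverseCrimeWarning,
            stacklevel=2,
        )
    A_fine = build_system_matrix(phantom_fine.grid, ring, acquisition, transducer)
    sino = A_fine.forward(phantom_fine)
    sino = add_awgn(sino, noise_spec)
    A_coarse = build_system_matrix(recon_grid, ring, acquisition, transducer)
    return sino, A_coarse
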