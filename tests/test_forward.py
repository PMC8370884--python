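"""Forward operator: geometry, adjointness, transducer filter, noise."""

import numpy as np
import pytest

from binpat.forward import (
    AliasingError,
    CoverageError,
    InverseCrimeWarning,
    NoiseSpec,
    TransducerModel,
    UndefinedSNRError,
    add_awgn,
    apply_transducer_response,
    build_system_matrix,
    forward,
    simulate_measurement,
)
from binpat.geometry import AcquisitionSettings, PressureImage, make_detector_ring, make_grid
from binpat.phantoms import PhantomSpec, generate_random_disks


def _point_image(grid, iy, ix, value=1.0):
    vals = np.zeros(grid.shape)
    vals[iy, ix] = value
    return PressureImage(grid=grid, values=vals)


def test_adjoint_identity(small_operator, rng):
    """<A x, y> == <x, A^T y> to 1e-10 relative, on 20 random pairs."""
    A = small_operator
    for _ in range(20):
        x = rng.standard_normal(A.n_cols)
        y = rng.standard_normal(A.n_rows)
        lhs = float(A.matvec(x) @ y)
        rhs = float(x @ A.rmatvec(y))
        denom = np.linalg.norm(A.matvec(x)) * np.linalg.norm(y)
        assert abs(lhs - rhs) <= 1e-10 * max(denom, 1e-300)


def test_forward_linearity_and_zero(small_operator, small_grid, rng):
    A = small_operator
    zero = PressureImage(grid=small_grid, values=np.zeros(small_grid.shape))
    assert not forward(A, zero).values.any()
    x1 = rng.standard_normal(small_grid.shape)
    x2 = rng.standard_normal(small_grid.shape)
    b12 = A.matvec((2.0 * x1 + 3.0 * x2).ravel())
    combo = 2.0 * A.matvec(x1.ravel()) + 3.0 * A.matvec(x2.ravel())
    np.testing.assert_allclose(b12, combo, rtol=1e-10, atol=1e-12 * np.abs(combo).max())


def test_point_source_arrival_sample():
    """A centre pixel seen by a detector at 22 mm peaks at sample ~293
    (0.022 m / 1500 m/s / 50 ns = 293.3)."""
    grid = make_grid(3, 3, 0.1)
    ring = make_detector_ring(1, 22.0)
    A = build_system_matrix(grid, ring, AcquisitionSettings(), transducer=None)
    trace = A.forward(_point_image(grid, 1, 1)).values[0]
    assert np.argmax(trace) == 293
    # bilinear split: the two adjacent bins carry all the energy
    assert trace[293] > trace[294] > 0


def test_shape_mismatch_rejected(small_operator):
    grid = make_grid(8, 8, 0.5)
    with pytest.raises(ValueError):
        small_operator.forward(PressureImage(grid=grid, values=np.zeros((8, 8))))


def test_coverage_error():
    grid = make_grid(16, 16, 1.0)
    ring = make_detector_ring(4, 22.0)
    with pytest.raises(CoverageError):
        build_system_matrix(grid, ring, AcquisitionSettings(n_samples=16))


def test_rotational_symmetry(acquisition):
    """Centred disk + equally spaced ring: all traces identical.

    Four detectors at 90 degree spacing, matching the exact symmetry group of
    the rasterized disk (pixelation breaks continuous rotational symmetry, so
    only the grid's own rotations can be tested to tight tolerance).
    """
    grid = make_grid(64, 64, 20.1 / 64)
    ring = make_detector_ring(4, 22.0)
    A = build_system_matrix(grid, ring, acquisition, TransducerModel())
    X, Y = grid.pixel_centers()
    disk = PressureImage(grid=grid, values=np.where(X**2 + Y**2 <= 3.0**2, 1.0, 0.0))
    traces = A.forward(disk).values
    scale = np.abs(traces[0]).max()
    for d in range(1, ring.n_detectors):
        np.testing.assert_allclose(traces[d], traces[0], atol=1e-6 * scale)


def test_translation_shifts_energy_centroid(acquisition):
    """Moving a point source toward the detector advances its trace by
    delta / (c dt) samples (+- 1)."""
    grid = make_grid(41, 41, 0.2)
    ring = make_detector_ring(1, 22.0)  # detector at (22, 0)
    A = build_system_matrix(grid, ring, acquisition, transducer=None)
    t_a = A.forward(_point_image(grid, 20, 30)).values[0]  # x = +2.0 mm
    t_b = A.forward(_point_image(grid, 20, 20)).values[0]  # centre

    def centroid(tr):
        w = tr**2
        return float((w * np.arange(len(tr))).sum() / w.sum())

    shift = centroid(t_b) - centroid(t_a)
    expected = 2.0 / (acquisition.c_mm_us * acquisition.dt * 1e6)  # 26.7 samples
    assert abs(shift - expected) <= 1.0


def test_row_sparsity_bound(small_operator, small_grid):
    """Each row touches at most ~one circle's worth of pixels."""
    G = small_operator.G
    nnz_per_row = np.diff(G.indptr)
    circumference_px = 2 * np.pi * small_grid.half_diagonal / small_grid.dx
    assert nnz_per_row.max() <= 4 * circumference_px


# --- transducer ------------------------------------------------------------


def test_band_edges():
    tr = TransducerModel(center_frequency=2.25e6, fractional_bandwidth=0.7)
    assert tr.f_max == pytest.approx(3.0375e6)
    assert tr.f_min == pytest.approx(1.4625e6)
    # -6 dB (amplitude 1/2) at both edges, unity at fc
    resp = tr.amplitude_response(np.array([tr.f_min, tr.center_frequency, tr.f_max]))
    np.testing.assert_allclose(resp, [0.5, 1.0, 0.5], rtol=1e-12)


def test_dc_removed_and_tone_passes(small_ring, acquisition):
    tr = TransducerModel()
    const = np.ones((small_ring.n_detectors, acquisition.n_samples))
    from binpat.forward import Sinogram

    sino = Sinogram(values=const, ring=small_ring, acquisition=acquisition)
    filtered = apply_transducer_response(sino, tr)
    assert np.abs(filtered.values).max() < 1e-6  # DC killed

    # pure tone at the FFT bin closest to fc passes at >= 0.99 of passband max
    freqs = np.fft.rfftfreq(acquisition.n_samples, acquisition.dt)
    k = int(np.argmin(np.abs(freqs - tr.center_frequency)))
    t = np.arange(acquisition.n_samples) * acquisition.dt
    tone = np.cos(2 * np.pi * freqs[k] * t)
    sino_tone = Sinogram(
        values=np.tile(tone, (small_ring.n_detectors, 1)),
        ring=small_ring,
        acquisition=acquisition,
    )
    gain = np.abs(apply_transducer_response(sino_tone, tr).values).max() / np.abs(tone).max()
    assert 0.99 <= gain <= 1.0 + 1e-9


def test_aliasing_guard(small_ring):
    acq = AcquisitionSettings(dt=200e-9)  # Nyquist 2.5 MHz < f_max 3.0375 MHz
    from binpat.forward import Sinogram

    sino = Sinogram(
        values=np.zeros((small_ring.n_detectors, acq.n_samples)),
        ring=small_ring,
        acquisition=acq,
    )
    with pytest.raises(AliasingError):
        apply_transducer_response(sino, TransducerModel())


# --- noise -----------------------------------------------------------------


def test_awgn_realized_snr(small_ring, acquisition, rng):
    from binpat.forward import Sinogram

    signal = rng.standard_normal((small_ring.n_detectors, acquisition.n_samples))
    sino = Sinogram(values=signal, ring=small_ring, acquisition=acquisition)
    noisy = add_awgn(sino, NoiseSpec(snr_db=30.0, rng_seed=4))
    noise = noisy.values - signal
    realized = 20 * np.log10(
        np.sqrt(np.mean(signal**2)) / np.sqrt(np.mean(noise**2))
    )
    assert 29.5 <= realized <= 30.5
    assert noisy.noise == {"snr_db": 30.0, "seed": 4}


def test_awgn_clean_deterministic_and_errors(small_ring, acquisition, rng):
    from binpat.forward import Sinogram

    signal = rng.standard_normal((small_ring.n_detectors, acquisition.n_samples))
    sino = Sinogram(values=signal, ring=small_ring, acquisition=acquisition)
    clean = add_awgn(sino, NoiseSpec(snr_db=None))
    np.testing.assert_array_equal(clean.values, signal)
    assert clean.noise is None
    a = add_awgn(sino, NoiseSpec(snr_db=40.0, rng_seed=9))
    b = add_awgn(sino, NoiseSpec(snr_db=40.0, rng_seed=9))
    np.testing.assert_array_equal(a.values, b.values)
    zero = Sinogram(
        values=np.zeros_like(signal), ring=small_ring, acquisition=acquisition
    )
    with pytest.raises(UndefinedSNRError):
        add_awgn(zero, NoiseSpec(snr_db=30.0))


# --- simulate_measurement --------------------------------------------------


def test_simulate_measurement_fine_coarse(acquisition, transducer):
    fine = make_grid(64, 64, 20.1 / 64)
    coarse = make_grid(32, 32, 20.1 / 32)
    ring = make_detector_ring(8, 22.0)
    phantom = generate_random_disks(fine, PhantomSpec(family="disks", rng_seed=2))
    sino, A = simulate_measurement(
        phantom, ring, acquisition, transducer, NoiseSpec(snr_db=None), coarse
    )
    assert sino.values.shape == (8, 512)
    assert A.shape == (8 * 512, 32 * 32)
    assert sino.noise is None  # clean flag recorded

    with pytest.warns(InverseCrimeWarning):
        simulate_measurement(
            phantom, ring, acquisition, transducer, NoiseSpec(snr_db=None), fine
        )
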