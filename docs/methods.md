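# Methods

This note documents the models, numerical choices and known limitations of
`binpat`. Everything quantitative here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not measure.

## Forward model

The acoustic forward map is a discretized circular-mean (circular Radon)
projection. For detector `d` at ring position `r_d` and pixel `p` at centre
`x_p`, the arrival time is `t = |x_p − r_d| / c` with a homogeneous speed of
sound `c` (default 1500 m/s, stored in SI and converted once to mm/µs). The
pixel's weight is split linearly between the two adjacent time bins
(sub-sample accuracy without resampling), and carries the factor
`dx² / (2π r c Δt)` — pixel area converted to arc density with 1/(2πr)
cylindrical spreading, `r` clamped at half a pixel. Rows are ordered
detector-major; the matrix is stored in CSR. Time starts at the excitation
pulse (`t0 = 0`). Building the operator is deterministic and loop-free per
detector.

The default sampling (512 samples at 50 ns) covers the farthest pixel of the
20.1 mm field of view from a 22 mm ring with margin; the builder raises a
coverage error otherwise. On the protocol grids the operator shapes are
30 720×40 401 (60 detectors, 201² pixels), 40 960×40 401 (80 detectors) and
51 200×40 000 (100 detectors, 200² pixels).

### Transducer

The detector element is modelled as a zero-phase filter applied along the
time axis of each trace, with a Gaussian amplitude response: unity at the
centre frequency `fc` (default 2.25 MHz), −6 dB at the band edges
`fc (1 ± bw/2)` (default 70% fractional bandwidth, hence a maximum detectable
frequency of 3.0375 MHz), and the DC bin removed exactly. The filter is
implemented as a real multiplication in the rFFT domain, which makes it
exactly self-adjoint, so the composed operator `A = F G` still passes the
adjoint test to 1e−10.

One parameter goes beyond the textbook Gaussian: a **stop-band rejection
floor** (default 0.25 in amplitude, i.e. −12 dB) below the centre frequency.
An idealized Gaussian at 70% bandwidth is ~−49 dB near DC; with it, the
interior of any absorber larger than about half an acoustic wavelength
(λ/2 ≈ 0.33 mm here) contributes essentially nothing to the data, every
reconstruction — linear or binary — degenerates to rims, and the comparative
behaviour of the four methods collapses. Physical single-element transducers
leak low-frequency energy at a finite stop-band level rather than a Gaussian
tail; modelling that floor restores the qualitative regime in which smooth
solvers refill blob interiors. The floor does not touch the −6 dB band
edges, the response at `fc`, or the DC removal. Setting
`stopband_rejection=0` recovers the pure Gaussian.

The same filtered operator is used for simulation (on the fine grid) and
inversion (on the coarse grid); the transducer is part of the physics, not of
one particular solver.

### Noise

Additive white Gaussian noise is calibrated globally on the sinogram in
amplitude-ratio decibels: `σ = rms(b) / 10^(SNR/20)`. The realization is a
pure function of the seed. The study uses 30/40/60 dB.

### Inverse-crime control

Data are always simulated on a finer grid (default 201², 0.1 mm) than the
inversion grid (default 101², ≈0.199 mm). Running both on the same grid is
allowed but flagged with a warning. The desk-scale pair (201²/101²) halves
the full-scale grids (402²/201²) to keep every benchmark cell in seconds to a
couple of minutes on one CPU; the full-scale pair runs unchanged through the
same API if wanted.

## Phantoms

All phantoms are pure functions of `(grid, spec)` — bit-identical on repeat —
and strictly two-valued `{0, amplitude}` (pixel-centre-inside rasterization,
no anti-aliasing), because the evaluation needs an exact binary ground truth.
The default amplitude is 1 kPa.

* **Derenzo-style disks** — six 60° sectors of triangular-lattice disks with
  per-sector radii {1.6, 1.3, 1.05, 0.85, 0.65, 0.5} mm, centre spacing twice
  the diameter, everything inside a 9 mm circle. The smallest disks sit at
  the λ/2 resolution limit of the 2.25 MHz transducer, so the phantom spans
  "comfortably resolved" to "barely resolvable". The generator validates
  non-overlap and field-of-view containment, and warns when rasterized on a
  grid too coarse for the smallest disks.
* **Vessel tree** — a seeded recursive branching walk: two children per
  node, radius decay 0.75, length decay 0.85, random turn angles of 15–40°,
  rasterized as thick capsules. Default depth 5 gives a foreground fraction
  of a few percent, mimicking sparse vasculature.
* **Random disks** — 3–6 non-overlapping disks of 1.2–2.8 mm radius placed
  uniformly; used for parameter-recovery tests.

## Solvers

All solvers are matrix-free (only `matvec`/`rmatvec`), deterministic, and
retain negative values in their output; clipping happens only in evaluation.

* **Backprojection** is the plain adjoint `Aᵀb`, one pass.
* **Tikhonov** minimises `‖Ax−b‖² + λ‖x‖²` by conjugate gradients on the
  damped normal equations (CGLS). The objective is recorded per iteration
  and is non-increasing; it matches a dense normal-equations solve to 1e−6
  relative error up to 400 unknowns (tested). Default stop: relative
  gradient below 1e−6 or 300 iterations.
* **L1** minimises `‖Ax−b‖² + λ‖x‖₁` by majorization-minimization, i.e.
  soft-thresholded gradient steps
  `x ← soft(x + (1/c) Aᵀ(b − Ax), λ/(2c))` with the step constant
  `c = 1.05 × λ_max(AᵀA)` from 20 power iterations — this keeps the
  surrogate a true majorizer, so the objective is monotone; a repeated
  increase (possible only with a user-supplied `c`) raises a step-size error.
* **λ selection**: the study selects λ by a coarse sweep maximising Dice
  against the known truth (simulation mode only), mirroring a
  figure-of-merit-driven heuristic choice. Default grids:
  `λ ∈ {2,5,10,20,50}·10⁻⁴ · ‖A‖²` for Tikhonov; for L1 the grid is
  expressed through the ISTA threshold `λ/(2c)` as
  {0.3, 1, 3, 10}% of the absorber amplitude.

### Binary tomography

The two-level constraint `x ∈ {u0, u1}` is dualized; the solver iterates

```
v ← S_asym( v + τ x̂(v) ;  τ a', τ b' ),     x̂(v) = argmin_x ½‖Ax−b‖² + ε/2‖x‖² + vᵀx
```

with `a' = (1−δ)|u0|`, `b' = (1−δ)|u1|`, monitoring the dual objective
`−[½‖Ax̂−b‖² + ε/2‖x̂‖² + vᵀx̂] + p(v)` and halving τ whenever it would
increase (backtracking). Numerical choices, each of which mattered:

* **Inner solves** are damped CGLS (`ε = 10⁻⁴‖A‖²` by default; zero for
  well-posed toy problems), warm-started from the previous iterate and run
  to a gradient tolerance of 1e−7. Accuracy here is not cosmetic: the dual
  objective is minus an inner *minimum*, so an unconverged inner solve
  underestimates it, and comparing a stale underestimate against later,
  better-solved iterates makes backtracking reject every step. The cold
  start therefore gets a 4× iteration budget.
* **Step size** starts at `τ = 10⁻³‖A‖²` and only shrinks (backtracking);
  the dual objective trace is non-increasing by construction.
* **Level margin** `δ = 0.01`: the prox thresholds use slightly shrunk
  levels. Without it the noiseless self-consistent case is degenerate — the
  tilted least-squares value of a true absorber pixel sits exactly at `u1`,
  the dead-zone boundary, the dual optimum is `v* = 0` there, and with the
  `H(0) = 0` convention the pixel falls to background. The margin breaks the
  tie toward the absorber class while shifting the noisy-data operating
  point by only 1% of the level.
* **Heaviside convention** `H(0) = 0` and initialization `v⁰ = 0`:
  undecided pixels are background, the conservative class for vasculature
  maps.
* **Stopping**: relative dual-objective change below 1e−6 or 200 iterations.
  The support typically stabilizes long before the objective does.

At stationarity the solver has found a tilt `v` under which the penalized
least-squares solution equals `(1−δ)u1` wherever `v > 0` and lies in
`[−|u0|, (1−δ)u1]` elsewhere — so `u1` acts as the effective
absorber/background decision level. That is why **level estimation**
matters: `estimate_levels` sets `u0 = 0` and `u1` to the *mean intensity of
the provisional foreground* (clip-at-zero + mean-threshold) of a quick
30-iteration Tikhonov reconstruction. With a bandlimited operator this lands
at ~0.6–0.7 of the true amplitude for 1 kPa phantoms — below the peak, which
is exactly where the decision level should sit. A peak-oriented estimate
(e.g. a high percentile) systematically undercalls absorber rims. Explicit
user levels always bypass estimation.

On the exhaustively enumerable scale (2×2 and 3×3 grids, dense
well-conditioned operators, noiseless data) the solver attains the residual
of the true binary minimiser over all 16/512 candidates to 1e−6 (tested).

## Evaluation

* **Dice** `2|X∩Y|/(|X|+|Y|)`; undefined (error) when both masks are empty.
* **Clip + mean threshold** (benchmark default for the comparators): clip
  negatives to zero, foreground strictly above the mean of the clipped image
  taken over *all* pixels.
* **Two-class k-means** on intensities (used for the visual FP/FN overlays),
  with deterministic min/max centroid initialization — no RNG in evaluation.
* Binary-solver outputs are scored directly on their upper level set; they
  are already segmentations.
* FP/FN overlays are rendered green/pink over white true positives; line
  profiles are bilinear samples with physical coordinates.

## Benchmark behaviour and known limitations

The packaged benchmark (Derenzo phantom, 80 detectors, 30 dB, desk scale)
lands at approximately Dice 0.32 / 0.85 / 0.95 / 0.97 for
backprojection / Tikhonov / L1 / binary, with the strict ordering
bp < Tikhonov < L1 < binary stable across 30/40/60 dB and the scores nearly
noise-insensitive (the limiting factors are bandwidth and view count, not
noise).

* **Backprojection scores low under the mean threshold.** The adjoint image
  carries the classic 1/|x| halo of unfiltered backprojection plus a broad
  positive pedestal; the clipped-image mean falls well below the optimal
  cut, so the protocol over-segments by roughly 4×. This is a property of
  scoring a raw adjoint with a global mean threshold, not of the solver
  implementation: across every adjoint variant tried (geometric or filtered,
  1/r or pure interpolation weights, matched-filter/derivative models,
  the 2p − 2t∂p/∂t delay-and-sum weighting, fine grids) the mean-threshold
  Dice stays in 0.2–0.45 even when the best possible threshold on the same
  image reaches 0.8.
* **Tikhonov** peaks near 0.85 under this protocol; smooth positives around
  the disks keep the mean threshold permissive.
* The synthetic study is ray-based: no full-wave propagation, no acoustic
  attenuation or dispersion, no finite detector aperture, no heterogeneous
  speed of sound, no fluence variation. Passing benchmarks here demonstrates
  the solvers' behaviour under the stated discrete model, not performance on
  experimental data. Externally acquired sinograms can be imported through
  the HDF5 container, but no claims are made for them.
* The binary method presumes exactly two tissue classes; multi-level
  absorber distributions are out of scope.

## Determinism and seeds

Phantom generation, noise, and all solvers are pure functions of their
inputs and explicit seeds; the only RNG in the linear algebra is the seeded
start vector of the power iteration (fixed seed 0). Rerunning any pipeline
command with the same config yields byte-identical outputs, and
`scripts/acceptance.py --seed N` is exactly reproducible.
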