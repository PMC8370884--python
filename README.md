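# binpat — binary photoacoustic tomography

`binpat` reconstructs two-dimensional photoacoustic tomography (PAT) images
whose pixels are constrained to exactly two levels — background and absorber —
**directly from the sinogram**, so that the reconstruction *is* the
segmentation. It is aimed at vasculature imaging, where the quantity of
interest is the support of the vessels rather than the continuous pressure
amplitude, and at anyone comparing discrete-tomography ideas against the
standard linear PAT reconstructions. The package ships the three usual
comparators (backprojection, Tikhonov, L1 sparse recovery), a circular-Radon
forward model with a bandlimited transducer, synthetic Derenzo/vessel/disk
phantoms, and a Dice-based evaluation harness for in-silico benchmarking.

## The model

PAT measures time-resolved acoustic traces `b` at detector positions on a
ring; discretizing the circular-mean projection gives the linear forward
model

```
A x = b,        A ∈ R^(NM×NP),  NM = n_detectors · n_samples,  NP = nx · ny
```

where `x` is the initial pressure rise. The comparators solve

* backprojection: `x_bp = Aᵀ b`
* Tikhonov:       `min_x ‖Ax − b‖² + λ‖x‖²`
* L1 (MM/ISTA):   `min_x ‖Ax − b‖² + λ‖x‖₁`

The binary method constrains `x ∈ {u0, u1}^NP` (`u0 < u1`) through an
auxiliary sign variable and solves the **convex dual** in the Lagrange
multiplier `v`:

```
min_v  h(v) + p(v),     h(v) = −min_x [ ½‖Ax − b‖² + vᵀx ],
p(v) = Σᵢ |u0|·max(−vᵢ,0) + |u1|·max(vᵢ,0)          (asymmetric one-norm)
```

by proximal gradient descent — the gradient of `h` is `−x̂(v)` (a tilted
least-squares solve), and the proximal operator of `p` is the **asymmetric
soft-threshold** `S(t) = t−|u1|` for `t ≥ |u1|`, `t+|u0|` for `t ≤ −|u0|`,
else `0`. The two-level image is recovered by the Heaviside map
`x* = u0 + (u1 − u0) H(v*)`. Overlap with the ground truth is scored with the
Dice coefficient `DC = 2|X∩Y| / (|X|+|Y|)`.

## Worked example

Simulate the Derenzo-style resolution phantom (1 kPa disks, 20.1 mm field of
view) with 80 detectors on a 22 mm ring at 30 dB data SNR, and reconstruct it
directly as a two-level image:

```python
import binpat as bp

fine = bp.make_grid(201, 201, 0.1)           # forward grid, 20.1 mm FOV
coarse = bp.make_grid(101, 101, 20.1 / 101)  # inversion grid (no inverse crime)
spec = bp.PhantomSpec(family="derenzo", amplitude=1000.0)
phantom = bp.generate_derenzo(fine, spec)
ring = bp.make_detector_ring(80, 22.0)
sino, A = bp.simulate_measurement(
    phantom, ring, bp.AcquisitionSettings(), bp.TransducerModel(),
    bp.NoiseSpec(snr_db=30.0, rng_seed=0), coarse,
)

result = bp.BinaryTomography(A, sino).fit()   # levels estimated from the data
print(result.summary())

truth = bp.generate_derenzo(coarse, spec)
print(bp.compare_masks(truth, result.image, method="binary").summary())
```

which prints

```
sinogram (80, 512), operator (40960, 10201)
                  Reconstruction summary
==========================================================
method:               binary
unknowns:             10201
lambda:               0
iterations:           200
converged:            False
residual ||Ax-b||:    187.08
min / max value:      0 / 665.698
final objective:      -2421.9
==========================================================
method=binary dice=0.9764 |true|=826 |recon|=827 |FP|=20 |FN|=19
```

The solver estimated the absorber level at ≈ 666 Pa from the data, the output
takes exactly the two values {0, 666} Pa, and its support overlaps the true
mask with Dice 0.976 — 826 true against 827 reconstructed foreground pixels
with 20 false positives and 19 false negatives. (The `converged: False` flag
means the dual objective was still improving at the iteration cap; the
support itself is stable well before that.)

The same pipeline is scriptable from the shell:

```bash
pat simulate   --config run.yaml --out sim/
pat reconstruct sim/sinogram.h5 --method binary --out rec/
pat evaluate   rec/recon_binary.tif sim/ground_truth.tif --out metrics/
pat benchmark  --detectors 80 --snr 30 --snr 40 --snr 60 --out table.csv
```

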