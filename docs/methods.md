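# Methods

## Forward model

A tilt series is modeled as parallel-beam projection of a density volume
v ∈ R^{x×y×z} about the y-axis: p = Pv, with one x×y image per tilt angle.
At 0° the beam runs along +z; a positive angle rotates the beam from +z
toward +x (right-handed about +y). The discrete operator samples the volume
by bilinear interpolation in the xz-plane at unit steps along each ray
(samples outside the volume contribute zero); rays never leave their
y-plane, so P acts independently on every y-slice. P is materialized as a
sparse matrix per (x, z, angles), which makes the adjoint exact (P^T) and
the whole model linear and differentiable — gradients of any loss on Pv are
P^T applied to the data-space gradient. Voxel centers sit at integer
indices with the volume centered at ((x−1)/2, (y−1)/2, (z−1)/2).

Restricting tilts to ±β leaves a double wedge of Fourier space unsampled
(the "missing wedge"), the cause of z-elongation and top/bottom blur in
standard reconstructions.

## Reconstruction

The estimate is an implicit neural representation: a coordinate network
G_θ: [−1,1]³ → R evaluated on the voxel-center grid, fitted by

    θ* = argmin_θ ‖p − P G_θ(C)‖²_W + λ·R(G_θ(C)),

with Adam and a log-decayed (geometric) learning-rate schedule. The network
is a sine-activated MLP: positional encoding with L = 6 octaves
([sin(2^k π c), cos(2^k π c)], raw coordinate prepended; 39 input features),
an input layer to the hidden width, `hidden_layers` hidden-to-hidden layers,
and a linear scalar output. All sine layers compute sin(ω0·(Wx+b)) with
ω0 = 30; the first layer is initialized U(±1/fan_in), deeper layers
U(±√(6/fan_in)/ω0), the spread that keeps sine pre-activations
well-distributed at depth. The default architecture has 4 hidden layers of
256 features; its nominal capacity is counted as hidden_layers·features²
(262,144 for the default) — the convention used for capacity budgeting —
while the true trainable count (input/output layers and biases included) is
reported in run logs.

### Weighted data fidelity

‖·‖_W is a mean squared error whose residual spectrum is weighted by |f|
along the detector axis (the ramp of weighted back projection), with the
weight floored at the first nonzero frequency and normalized to unit mean.
The plain (unweighted) MSE landscape of P is badly conditioned — the
operator's spectrum decays like 1/|f|, so gradient descent fits low
frequencies quickly and then stalls: at the 2000-iteration budget the
unweighted fit remains visibly short of data consistency (reprojection MSE
~2·10⁻³ on the fixture below, present-region FSC 0.66), even though the same
network fitted *directly* to the volume reaches 64 dB in under 1200
iterations. The ramp weighting acts as a preconditioner and restores
data-consistent fits (reprojection MSE ~10⁻⁵) within the same budget. Plain
MSE remains available via `FitConfig(fidelity_weighting="none")`.

λ defaults to 0; the one built-in regularizer is a smoothed anisotropic
total variation (mean of √(d²+ε), ε = 10⁻⁸) on the estimated subvolume.

### Subvolume partitioning and learned initialization

To keep a constant budget of nominal network parameters per reconstructed
voxel (default ratio 1/8), the series is split into width-j subslices along
y, j being the largest power of two with nominal_params/(x·j·z) ≥ ratio,
clamped to [1, y] (a 1024×1024×256 volume with the default network gives
j = 8, i.e. 128 subvolumes; the last subslice may be narrower when y is not
divisible by j). One network is fitted per subvolume, in y-order. The first
is fitted cold for 2000 iterations (lr 10⁻³ → 10⁻⁴); every subsequent
network starts from its neighbor's fitted weights and runs 400 iterations
(lr 10⁻⁴ → 10⁻⁵). Fitted subvolumes are stitched by direct concatenation —
no blending — which deliberately reproduces the y-streak regime of the
partitioned method; an overlap-blend is intentionally not provided.

Warm-start transfer is strongest when adjacent subvolumes share most of
their structure, as they do at reference scale (j/y < 1%). At desk scale
(j/y = 50% on the test fixture) roughly half the scene is new to each
adjacent fit, and 400 low-learning-rate iterations recover data consistency
only partially: warm-started fits still start ~5× lower and end ~5× better
than an equal-budget cold fit, but do not reach the loss level of a full
cold 2000-iteration fit. This is a known scale artifact of the partition,
not of the representation.

### Per-step coordinate batching

`FitConfig.coords_per_step` limits the coordinates evaluated per iteration.
Batches are whole y-slices: because rays never cross y-planes, the
projection loss restricted to a random subset of slices is exact on that
subset and its expected gradient equals the full gradient. The desk-scale
fixture uses 16384 coordinates/step (8 of 32 slices); "all" evaluates the
full grid every step.

## Synthetic data

Two binarized slab phantoms (z < x, y, mimicking objects in a thin ice
layer): hollow spherical shells of uniform-random diameter (shell thickness
10% of diameter, ≥ 2 voxels; a voxel belongs to a shell iff its center lies
within [outer−thickness, outer] of the sphere center), and a mixed-shape
family (full spheres, ellipsoids, pyramids, cubes, rectangular prisms,
discs, 4- and 6-pointed 3D crosses; object i takes class i mod 8, so any
phantom with ≥ 8 objects covers all classes). Placement is uniform with the
whole object inside the volume; overlap is allowed by default. Box-like
shapes snap to the voxel grid so that a side-s cube covers exactly s³
voxels. Phantoms are low-pass filtered with a radial Gaussian window
(half-power at the cutoff, default 0.25 of Nyquist) to smooth surfaces,
clamped to non-negative values, and rescaled to [0,1]; tilt series are
normalized to [0,1] globally (per-stack, not per-image, to preserve
inter-tilt consistency).

Object density is set to a projected areal coverage of roughly 0.4 of the
xy field (150 objects of diameter 16–64 at 1024×1024×256; 14 objects of
diameter 8–16 on the 64×64×32 test fixture), emulating a crowded single
layer of discrete particles.

The generator emulates geometry only. It does not model shot noise, the
contrast transfer function, dose-dependent damage, misalignment, or
per-tilt intensity variation; passing tests therefore demonstrate correct
missing-wedge behavior of the *reconstruction machinery* on clean data, not
robustness on experimental tilt series.

## Evaluation

* **PSNR** 10·log₁₀(Im²/MSE), Im defaulting to the reference maximum;
  identical volumes report infinity.
* **SSIM** mean local structural similarity with a 3D Gaussian window
  (σ = 1.5, 11³ support, K1 = 0.01, K2 = 0.03, no sample covariance),
  dynamic range from the reference, computed in 3D (not slice-averaged).
* **VIF** pixel-domain multiscale visual information fidelity extended to
  3D (4 dyadic scales, Gaussian-scale-mixture scene model, noise variance
  2.0); 1 for identical volumes, (0,1) for blur, > 1 for contrast
  enhancement; undefined (error) for a constant reference.
* **FSC** per-shell normalized correlation of Fourier coefficients without
  mean subtraction, unit-width shells with a voxel assigned to round(|k|)
  (|k| in Fourier-voxel units of the largest axis), radius 1 to Nyquist.
  Shells whose energy is numerically zero (power < 10⁻²⁴ of the volume's)
  report correlation 0 rather than a 0/0 of round-off noise.
* **Directional FSC**: a Fourier grid point is "present" iff it lies within
  half a Fourier voxel of some acquired central plane, i.e.
  min_θ |k·n(θ)| ≤ 0.5 with beam direction n(θ) = (sin θ, 0, cos θ);
  "missing" is the complement. Both masks are Hermitian-symmetric and
  partition the grid; nearest-grid-point membership is used with no
  interpolation across the slab boundary. The FSC restricted to the missing
  region measures exactly the information a method must restore.
* **z-elongation**: volumes are thresholded at half their maximum, labeled
  into connected components, and the voxel-weighted mean of (std of z
  coordinates)/(std of x coordinates) over components of ≥ 20 voxels is
  reported; isotropic content gives ≈ 1, wedge artifacts inflate it.

Before voxel metrics, each reconstruction is affine-aligned (least-squares
scale and offset) to the [0,1] ground truth. Reconstruction scales are
arbitrary — the network fits [0,1]-normalized projections, so its volume
lives at roughly gt/(maximum path integral), and WBP's scale depends on the
filter gain — and fitting the two free constants puts all methods on one
footing. FSC is scale- and offset-invariant (offset affects only the
excluded DC term).

## Problem sizes and numerics

Tests validate the method on a 64×64×32 fixture (14 hollow spheres,
α = 2°, β = 60°, 61 projections, reduced 2×64 network, j = 32, two
subvolumes, 2000/400 iterations, 16384 coordinates/step) — sizes chosen so
the whole suite runs on a single CPU in minutes. On that fixture the
coordinate-network reconstruction beats the in-repo WBP baseline on PSNR
(19.5 vs 19.2 dB), SSIM (0.43 vs 0.35), missing-region FSC averaged below
half-Nyquist (0.32 vs 0.13), and z-elongation (0.69 vs 0.75; ground truth
0.59). WBP remains stronger in the present region (0.95 vs 0.86) — at desk
scale, 61 noiseless projections make WBP nearly exact where it has data, so
whole-volume FSC can favor WBP even as the wedge-region and shape-fidelity
comparisons favor the network.

Fitting runs in float32 (the loss floor of interest, ~10⁻⁵, is far above
float32 precision); parameters are stored float64 at rest. Adam uses
β = (0.9, 0.999), ε = 10⁻⁸. All randomness derives from explicit integer
seeds (phantom placement, network init, slice batching); a run
configuration file fully determines a run. `lr_schedule` with fewer than
two total steps returns the starting rate. A constant tilt series
normalizes to all zeros with a warning. Degenerate planning inputs clamp to
a single subvolume.

## Known limitations

* Clean-data scope: no noise/CTF model (see above).
* Hard stitching produces y-seams at subvolume boundaries by design.
* The 400-iteration warm-start budget under-fits adjacent subvolumes when
  subslices are a large fraction of y (desk scale); at reference scale the
  partition is fine enough that this does not arise.
* Single-axis geometry only; no dual-axis or conical schemes, no projector
  alignment refinement.
* The WBP baseline is a minimal in-repo implementation (Fourier-domain ramp
  per image row, exact adjoint backprojection, 1/l scaling), adequate as a
  controlled baseline, not a replacement for production packages.
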