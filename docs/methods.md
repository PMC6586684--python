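# Methods

## Problem

Tissue electrical properties at radiofrequency — conductivity σ (S/m)
and relative permittivity ε_r — modulate how the MR transmit field
B₁⁺ propagates through the body, and change under pathology. MR
electrical properties tomography (MR-EPT) estimates σ and ε_r maps from
measurements of |B₁⁺| and of the transceive phase φ̃± — the only phase
a standard MR experiment gives access to. This package implements and
compares two reconstruction routes on simulated 3 T (128 MHz) data with
known ground truth:

* **H-EPT** — the analytic Helmholtz baseline,
  ε_r(r) = −Re(∇²B̃₁⁺/B̃₁⁺)/(μ₀ε₀ω²),
  σ(r) = Im(∇²B̃₁⁺/B̃₁⁺)/(μ₀ω),
  evaluated per voxel with a noise-robust derivative kernel;
* **DL-EPT** — a conditional GAN (U-Net generator, PatchGAN
  discriminator) trained on simulated acquisitions to map
  (|B₁⁺|, φ̃⁺, auxiliary channel) to a property map. The `cGAN_mask`
  variant uses a binary object mask as third channel; `cGAN_tissue`
  uses a pseudo spin-echo tissue-contrast image.

## Forward model

The electromagnetic solver is a 2D TM-polarized (Ez-only)
finite-difference frequency-domain Helmholtz solver:

    (∇² + ω²μ₀ε̃(r)) Ez = −iωμ₀ Jz,   ε̃ = ε₀ε_r − iσ/ω,

with the e^{+iωt} time convention, second-order 5-point Laplacian,
Dirichlet edges behind a 6-voxel conductive damping annulus (peak 2 S/m,
quadratic ramp), and a quadrature ring of 16 line sources at radius
0.35 m standing in for the dominant birdcage mode. One sparse LU
factorization serves two right-hand sides: the co-rotating transmit
drive (phases −φ_n), from which B₁⁺ = (Bx+iBy)/2, and the reversed
drive, whose field gives the receive sensitivity B₁⁻. The transceive
phase is φ̃± = arg(B₁⁺B₁⁻), unwrapped in 2D, and the transmit phase
assumption sets φ̃⁺ = φ̃±/2 — exact for circularly symmetric objects,
an honest error source for heads (see Limitations). Fields are gauged
so mean |B₁⁺| over the object is 1; every consumer is invariant to this
scale.

Verification: the interior of a homogeneous cylinder under circular
polarization is the Bessel mode B₁⁺(ρ) ∝ J₀(kρ) with
k² = ω²μ₀(ε₀ε_r − iσ/ω); the solver agrees with this closed form to
<2% in the interior at 2 mm spacing, and H-EPT applied to either field
recovers the input properties to well under 5%.

## Tissue models

Piecewise-constant 2D label maps with per-tissue literature values at
128 MHz (WM 0.34 S/m / 52.6, GM 0.59 / 73.4, CSF 2.14 / 84; tumor
analogue 1.4 / 73; agar phantom 0.88 / 80):

* **Phantoms** — 12 cm homogeneous disks. The library of 42 draws
  (σ, ε_r) pairs stratified-uniformly from σ ∈ [0.2, 2.2] S/m,
  ε_r ∈ [40, 90], ranges bracketing the named tissue and phantom
  values (stand-ins for a full per-model table).
* **Heads** — nested perturbed-ellipse shells (outer CSF rim 12 mm, GM
  ribbon 26 mm, WM core; elongation 1.05–1.2; sinusoidal boundary
  perturbations of low angular order) giving non-convex, spatially
  convoluted interfaces. Per-tissue values are the references
  perturbed by ±10% per model (±`eps_variation`); the canonical test
  head (seed 0, variation 0) carries the reference values exactly, and
  tumor experiments place a 1.5 cm disk inclusion in its WM core.
* **Pseudo spin-echo contrast** — fixed per-tissue intensities with
  CSF > GM > WM > air = 0, normalized to [0, 1].

## Noise model

Thermal noise is i.i.d. Gaussian on the real and imaginary parts of the
field; SNR is defined as in-mask mean magnitude over noise SD. The
default acquisition condition is magnitude SNR 90 with an independent
transmit-phase noise knob of SD 9×10⁻³ rad — the phase precision of
the emulated acquisition protocol, modeled as an independent Gaussian
knob on φ̃⁺ rather than through a full spin-echo noise chain. In SNR sweeps the phase SD
scales as 9×10⁻³ · 90/SNR so both channels degrade together.

## Helmholtz reconstruction

The Laplacian kernel is the least-squares second-order polynomial
(Savitzky–Golay-type) fit over a 7×7 support — the 2D counterpart of
the 7×7×5 noise-robust kernels used in volumetric practice. It annihilates constants and linear fields exactly, returns
exactly 2/h² on quadratics, and has a far smaller noise-amplification
factor (sum of squared weights) than the 5-point stencil. Voxels whose
kernel footprint crosses the object boundary are excluded from the
valid mask (boundary exclusion rather than extrapolation). ROI
statistics erode each tissue region with a 3×3-square structuring
element — an n-voxel erosion keeps exactly the voxels whose
(2n+1)-square neighborhood, i.e. the kernel footprint, lies inside the
region; the default depth is 3 voxels at 2 mm (6 mm), and coarser grids
use the physical-depth equivalent.

At 4 mm spacing the discrete Laplacian's symbol error mixes a small
fraction of the large conductive part of k² into its small real part,
biasing ε_r by ~10% for lossy objects; at the 2 mm default this drops
below ~3%. H-EPT evaluations therefore run at 2 mm or finer.

## Networks and training

The generator is a 3-level U-Net (stride-2 4×4 encoder convolutions,
nearest-neighbor upsampling with skip concatenations, instance
normalization, leaky ReLU, linear single-channel head); the
discriminator a 3-level PatchGAN over (input, map) stacks (~34-voxel
receptive field at 64², the classic ~70-pixel field scaled with the
image). Both are implemented in a compact numpy framework with manual
backpropagation (im2col convolutions lowered to single-GEMM BLAS calls)
— small enough to train on one CPU core, exact gradients verified
against finite differences in float64.

The objective is

    F = arg min_G max_D λ_GAN·L_GAN(G,D) + λ_L1·L1(G) + λ_L2·L2(G)

with defaults λ_GAN = 2, λ_L1 = 100, λ_L2 = 200 (the validation-selected
combination; tumor experiments use the heavier supervised weighting
2/1000/2000, also supported). λ_GAN = 0 degrades to plain supervised U-Net training used
as the ablation. Separate networks are trained for σ and ε_r.

Normalization: magnitude divided by its in-mask mean; phase centered on
its in-mask mean and expressed in quarter-turn units (rad/(π/4)) — with
a full-turn unit the phase channel's dynamic range sits an order of
magnitude below the magnitude channel's and the network measurably
under-uses it, leaving conductivity biases of ±10–20% on held-out
phantoms; targets scaled to [0, 1] over σ ∈ [0, 2.5] S/m and
ε_r ∈ [1, 100] and inverted at inference; air is forced to (0, 1).

Optimization: Adam (β₁ = 0.5), batch 8, learning rate 4×10⁻⁴ held for
the first half of training then decayed linearly to zero, with
stochastic weight averaging of the generator over the final quarter —
without these two stabilizers the held-out ROI mean oscillates by
several percent between late epochs under the adversarial term. When a
validation set is available (the split's validation phantoms), the
final weights are selected by validation NRMSE — the better of the
best post-decay epoch and the weight average — mirroring the study's
validation-driven model selection and suppressing occasional outlier
endpoints. All randomness (weights, shuffling, noise) derives from one
seed; training is bit-reproducible single-threaded.

## Desk-scale study configuration

The emulated database keeps the study's structure at reduced size,
with one deliberate rebalancing: the full-scale database pairs 42
phantoms with 25 z-slices each, and the z-slices of a real cylinder in
a birdcage sample genuinely different field curvatures per property
pair — an axis a 2D solver cannot emulate. The desk-scale library
therefore trades slices for property-space coverage: 80 phantoms × 2
jittered slices (in-plane shift ≤3 voxels, each slice with its own
solve and noise seed), keeping the canonical split ids (12, 24
validate; 38, 42 test; the test phantom carries the agar values
0.88 S/m / 80 that the full-scale evaluation reads against) — 76×2 =
152 training examples at 64×64 / 4 mm. Head networks train on 12
tumor-free head geometries × 4 wobble variations; geometry seed 0 is reserved for testing, and
training heads draw per-tissue properties widely (±40% around the
references — the training database must span broad ranges, as the
phantom library does, or the networks memorize per-tissue constants)
while evaluation heads keep the tight reference-anchored values. The
tumor-generalization networks follow the study's tumor configuration:
trained on all tumor-free models (phantoms and heads together) with
the heavier supervised weighting λ = (2, 1000, 2000).
Precision comparisons acquire the phantom at the full-scale in-plane
grid (256², 1 mm, cubic-spline refinement of the 2 mm solve, which
amply resolves the ~15 cm in-tissue wavelength): per-voxel noise
amplification of the derivative kernel scales as 1/h², so H-EPT's
precision must be quoted at the resolution it is expected to deliver,
while the scaled-down network operates at its native 64² grid. The
jitter amplitudes, slice counts, and network size are the smallest
configuration at which the held-out accuracy protocol is stable on one
CPU core; they are package design choices, not study parameters.

## What the generator does and does not emulate

The simulator reproduces: piecewise-constant dielectric geometry,
dielectric resonance brightening, conductive phase roll, transceive
phase asymmetry of non-symmetric objects, calibrated thermal noise, and
the boundary-error behavior of kernel-based H-EPT. It does not
reproduce: 3D field curvature (the 2D TM solve overstates in-plane
scattering and has no through-plane derivative term), anatomical
realism (skull, scalp, ventricles, gyri), B₁ mapping-sequence
systematics, CSF pulsation or motion. Passing tests therefore
demonstrate the method pipeline under controlled 2D conditions, not
clinical performance.

## Numerical choices and degenerate inputs

Singular Helmholtz systems raise with a diagnostic rather than
returning garbage; zero-field voxels are flagged invalid, not
NaN-propagated; ROI regions that vanish under erosion are dropped with
a warning; even kernel supports, overlapping dataset splits, degenerate
sampling ranges, tumor inclusions touching air, and channel-kind
mismatches at inference all raise explicit errors. Model-selection
ties break to the lowest candidate index.

## Known limitations

* **Tumor generalization does not reproduce at this scale.** Mask-variant
  networks trained on tumor-free phantoms and heads paint per-region
  prior values over a 1.5 cm inclusion (tumor-ROI conductivity near the
  white-matter value instead of 1.4 S/m), while the purely local
  Helmholtz reconstruction recovers the inclusion mean almost exactly.
  The scaled-down network evidently leans on global image context
  rather than the local field signature — a capacity/scale effect a
  full 256²-resolution network trained on a 2014-example database
  would not necessarily share. The tumor-comparison harness computes
  and reports this outcome as measured.

* The transceive-phase asymmetry of elongated heads is genuine physics
  the 2D stand-in slightly exaggerates relative to 3D: H-EPT GM
  permittivity errors scatter over ~2–12% across head geometries
  (median ~7%), straddling the 10% level expected of full-scale
  volumetric reconstructions.
* The scaled-down networks retain a few-percent property-interpolation
  bias on held-out phantoms (76 training pairs sample the (σ, ε_r)
  plane sparsely); it is held a few-fold below the 5% level by the
  widened pair coverage and the validation-based model selection.
* Permittivity H-EPT at coarse spacing carries the σ→ε_r symbol-mixing
  bias described above; evaluations avoid the regime.
* Only 128 MHz (3 T) is validated; constants are configurable but no
  dispersion model is included.
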