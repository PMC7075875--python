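# Methods

## Forward model

Multishot acquisition is modelled on a Cartesian N×N k-space grid covered
by S disjoint segment masks u_s (one per shot).  The corrupted measurement
is

    y = Σ_s U_s F C M_s(x),

where M_s applies the rigid motion of shot s in image space (rotation about
the geometric centre (N−1)/2 followed by translation, bilinear
interpolation, zero fill outside the frame), C multiplies by complex coil
sensitivities, F is the centred orthonormal 2-D DFT, and U_s keeps only
shot s's segment.  Shot 1 always carries zero motion: rotations are defined
relative to a reference pose, so the reconstruction of motionless data is
independent of S.  Motion is applied in image space before encoding rather
than as k-space phase ramps; the two are equivalent for translations but
not for rotations, and the image-space form keeps the model exact for
arbitrary rigid motion.

Two motion schedules are built in.  `constant_increment` ramps linearly
from 0 to the maximum rotation Δθ across the shots (for S=2 this is a
single inter-shot rotation of Δθ, the convention used in the trajectory
experiments); `random_uniform` draws each shot independently from
U(−Δθ, Δθ) with shot 1 pinned to zero.  Translations follow the same
schedules (default amplitude 0: head motion in axial brain slices is
predominantly rotational, and the experiment grids vary rotation only).

Orthonormal FFT scaling makes the encoding operator E and its adjoint an
exact adjoint pair (verified to ~1e-15 against brute-force inner products),
which in turn keeps the normal operator EᴴE Hermitian PSD and the Krylov
solver well-scaled.

## Coil model

Receiver sensitivities are broad complex Gaussians centred on a circle of
radius 0.6·N around the field of view (width 0.55·N, constant per-coil
phase), normalised so the sum of squared magnitudes is 1 at every pixel.
Under full sampling this makes EᴴE exactly the identity — convenient
analytically and representative of well-calibrated SENSE.  Default coil
count is 8 (a common head-array size); a single coil degenerates to a
uniform all-ones map.  Real measured maps (unnormalised, spatially varying
phase) are not emulated; the reconstruction accepts them, and the
preconditioner below exists for exactly that case.

## Reconstruction

CG-SENSE solves EᴴE x = Eᴴy matrix-free.  The iteration used is the
conjugate residual variant of the Hermitian Krylov family (same cost per
iteration as classical CG: one EᴴE apply) because it minimises the
residual norm over the Krylov space at every step, making the recorded
residual history non-increasing by construction; classical CG residual
norms can transiently grow on undersampled systems (observed factor-of-few
spikes on an 80 %-sampled N=16 system with condition number ≈100), which
would make the history useless as a convergence diagnostic.  The solution
matches a dense direct solve of the normal equations to <1e-6 relative
error on N=16 oracle problems.

Defaults: warm start x⁰ = Eᴴy, relative-residual tolerance 1e-6, at most
50 iterations, symmetric Jacobi preconditioning by the inverse square root
of the coil sum of squares (a no-op for the normalised simulated coils,
an intensity correction for measured maps).  The returned image is the
solution magnitude rescaled to [0, 1], which is what the corrector
consumes; the raw complex solution is also kept.

Note that in this pipeline the union of the shot masks always covers
k-space, so EᴴE = I and the solver converges immediately; the partial-mask
code paths are exercised by the oracle tests and support undersampled use.

## Adversarial corrector

The generator is an hourglass U-Net.  Encoder block i holds 5 convolutional
layers of n = base·2^i feature maps (middle layer n/2), stride 2 on the
first layer, leaky-ReLU (slope 0.2) activations, and a residual connection
from the first layer's output to the last layer's output.  Decoder blocks
mirror this with transposed convolutions and stride 2 on the last layer;
their residual shortcut links the first layer to the last stride-1 layer,
since the upsampling layer changes the spatial size.  Symmetric skips
concatenate each encoder output with the same-resolution decoder input.
No normalisation layers are used; the residual and skip paths are the
convergence mechanism.

A final 3×3 convolution produces a single channel that is **added to the
network input** and clipped to [0, 1]: the generator predicts an additive
artifact residual rather than synthesising the image.  This global identity
shortcut was adopted after measuring that a from-scratch generator with a
plain sigmoid output head converges far too slowly at desk scale — after
500 updates it reaches ~22 dB against inputs already at ~26 dB, i.e. the
"correction" degrades the image — whereas the residual head starts at input
quality and improves from there.  Residual prediction is the standard head
for restoration CNNs for exactly this reason.

The discriminator is the generator's encoder followed by global average
pooling and a single sigmoid unit giving P(real), output clamped to
[1e-7, 1−1e-7] for stable log-losses.

Losses.  The generator objective is the batch mean of
‖x_c − G(x_m)‖₂ + λ·log(1 − D(G(x_m))); the data term is the unsquared
per-image L2 norm.  λ defaults to 0.6 (the adversarial-weight grid search
of the underlying method favours values above 0.5).  The discriminator
minimises −[log D(x_c) + log(1 − D(G(x_m)))].  Internally the generator's
adversarial gradient uses the non-saturating form (ascend log D(G(x_m)));
the logged loss is the saturating expression above.

Schedule.  RMSProp (decay 0.9) at learning rate 1e-4 for both networks,
batch size 16, two discriminator updates per generator update, preceded by
an Adam warm start of the generator on the data term alone (default 200
steps).  One generator forward per adversarial step serves the fake batch
for both discriminator updates and the generator update itself — the
generator's parameters do not change between them, so this is exact, and it
roughly halves the per-step cost on CPU.

Desk-scale defaults: 32×32 inputs, 2 blocks, base 16 features (~84k
parameters).  A full-scale configuration (128×128, 4 blocks, base 64) is
expressible through the same config objects but is not exercised by the
test suite; the desk scale is what one CPU trains in minutes.

## Synthetic phantoms

Phantoms are randomised composites of soft-edged ellipses: a bright
skull-like ring, a uniform brain background, and n random interior
structures of varying intensity, plus one guaranteed off-centre blob so
every phantom is asymmetric under rotation.  Edge softness is chosen so
boundaries span ~2–3 pixels; with near-1-pixel edges the bilinear
rotate/unrotate interpolation error (MAE ≈ 0.02 at 7°) dominates the
motion signal, while the soft setting keeps it near 0.01.  Intensities are
max-normalised to [0, 1], matching the reference-peak convention of the
PSNR definition.

What the phantoms do *not* emulate: tissue-contrast statistics of real
T2-FLAIR, pathology, receive-field inhomogeneity, thermal noise (none is
added anywhere — the corruption studied is purely motion), or 3-D
structure.  Passing tests therefore demonstrate that the pipeline's
algebra, solver, training dynamics and metric ordering behave as designed
on piecewise-smooth anatomy-like images; they do not certify performance
on clinical data.

## Metrics

PSNR = 20·log₁₀(max(r)/√MSE) with the peak taken from the reference image
(identical images return an explicit +inf sentinel).  SSIM uses 11×11
Gaussian windows (σ=1.5), k1=0.01, k2=0.03, data range 1, evaluated at all
fully interior positions (a uniform-window option exists).  Artifact power
is Σ(|r|−|x|)²/Σ|r|², which depends only on magnitudes.  Set summaries
report mean and sample standard deviation (ddof=1; a single image reports
sd 0).

## Experiment orchestration and reproducibility

The pipeline runs grids of (Δθ, S, trajectory).  Every grid cell derives
its own seed from the master seed by SHA-256 hashing of the cell
coordinates, so cells are independently reproducible; each cell's HDF5
file stores the clean images, corrupted k-space, masks, per-image motion
parameters, and a provenance attribute block (conditions + seeds + config
JSON, excluding disk paths).  Files are written with HDF5 timestamp
tracking disabled, so identical runs are bit-identical.  Model checkpoints
are single npz archives (float32 parameters plus config/log JSON) whose
round trip reproduces forward outputs bit-identically.

Problem sizes used by the test suite and the acceptance script — 16×16 for
dense-oracle algebra, 64×64 for the motion-level curve (32 phantoms,
S=16, random trajectory), 32×32 with 128 training pairs and 500 updates
for the adversarial smoke task, 200 data-term updates per arm for the
transfer experiment — are the package's desk-scale study conditions: small
enough to rerun interactively, large enough that the qualitative orderings
(AP grows with Δθ; correction improves held-out PSNR and AP; a warm start
from a 16-shot model reaches the 4-shot from-scratch validation loss in a
fraction of the steps) are stable across seeds.

## Known limitations

- Through-plane (3-D) motion, non-rigid deformation, and noise sources
  other than motion are out of scope.
- Non-Cartesian (spiral/radial) and variable-density trajectories are not
  implemented; acquisition ordering within a shot is ignored.
- The CPU network core is single-threaded numpy; full-scale (128×128,
  base 64) training is expressible but impractically slow without a GPU
  framework.
- The conjugate-residual residual history is monotone in the preconditioned
  norm; with non-identity preconditioning (unnormalised measured coils) the
  reported history is monotone in that transformed norm, not the plain one.
- Random trajectories assign k-space points to shots uniformly; real
  scanners impose per-shot readout structure that this ignores.
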