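# mrimotion

Rigid inter-shot motion is the dominant artifact source in multishot brain
MRI: k-space is covered in S separate excitations, and if the head moves
between shots the segments become mutually inconsistent, producing ghosting
and blurring in the reconstructed image.  `mrimotion` implements a complete
retrospective motion-correction pipeline for this setting, runnable
end-to-end on synthetic brain-like phantoms with no external data:

1. **Forward corruption model** — per-shot rigid transforms of the image,
   multi-coil Fourier encoding, and segment-wise sampling:

       y = Σₛ Uₛ F C Mₛ(x)

   with Mₛ the rigid motion of shot s, C the coil-sensitivity weighting,
   F the centred orthonormal 2-D DFT, and Uₛ the binary segment mask of an
   encoding trajectory (Cartesian sequential, 1-D/2-D interleaved, or
   random).
2. **CG-SENSE reconstruction** — the SENSE normal equations
   `EᴴE x = Eᴴy` solved matrix-free by a preconditioned conjugate-residual
   Krylov iteration (monotone residual history, dense-oracle-verified).
3. **Adversarial correction** — a conditional GAN whose U-Net generator
   maps the artifact-bearing reconstruction `x_m` to a corrected image,
   trained with the composite loss
   `‖x_c − G(x_m)‖₂ + λ·log(1 − D(G(x_m)))` (λ = 0.6) against an
   encoder-shaped discriminator; RMSProp at 1e-4, batch 16, two
   discriminator updates per generator update, Adam warm start of the
   generator.  The network core (convolutions, transposed convolutions,
   backprop, Adam/RMSProp) is implemented in numpy and verified against
   finite differences.
4. **Quality metrics** — PSNR `20·log₁₀(max(r)/√MSE)`, windowed SSIM, and
   artifact power `AP = Σ(|r|−|x|)²/Σ|r|²`.

The package targets researchers prototyping motion-correction methods who
need a reproducible, dependency-light sandbox: every stage is deterministic
per seed, every dataset file carries provenance, and the synthetic phantom
generator stands in for real T2-FLAIR slices (which can optionally be read
from NIfTI via the same preprocessing: centre crop, resize to the target
grid, discard blank slices).

## Worked example

```python
import numpy as np
from mrimotion import (generate_phantom, make_scheme, make_motion,
                       simulate_coil_maps, forward_corrupt,
                       cg_sense_reconstruct, psnr, ssim, artifact_power)

x = generate_phantom(size=64, seed=0, n_ellipses=8)
coils = simulate_coil_maps(n_coils=8, grid_size=64)
scheme = make_scheme("random", n_shots=16, grid_size=64, seed=0)
motion = make_motion("constant_increment", n_shots=16, max_rotation=5.0)

y = forward_corrupt(x, motion, scheme, coils)          # corrupted k-space
x_m = cg_sense_reconstruct(y, coils).image             # artifact-bearing image

print(f"PSNR {psnr(x, x_m):.2f} dB  SSIM {ssim(x, x_m):.4f}  "
      f"AP {artifact_power(x, x_m):.2e}")
```

prints

```
PSNR 35.72 dB  SSIM 0.9635  AP 2.69e-03
```

— a 5° inter-shot rotation over 16 shots leaves the reconstruction with a
measurable artifact power of 2.7×10⁻³ relative to the motion-free phantom
(AP = 0 would be artifact-free; larger values mean stronger ghosting).

Training the corrector uses the scikit-learn estimator interface:

```python
from mrimotion import GANCorrector

est = GANCorrector(n_blocks=2, base_features=16, pretrain_steps=200,
                   max_steps=300, random_state=0)
est.fit(X_corrupted, y_clean)      # stacks of (n, N, N) images
corrected = est.predict(X_corrupted)
```

The same stages are available as a CLI for experiment grids
(`mrimotion simulate / reconstruct / train / correct / evaluate`), driven by
a YAML config of motion levels Δθ, shot counts S, and trajectories; each
grid cell becomes one HDF5 file with full provenance.

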