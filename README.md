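# proj2proj

Self-supervised low-dose CT reconstruction: train an image-domain denoiser
using noisy projections as their own targets, with no clean images or
normal-dose scans anywhere in the loop.

## The problem

Sparse-view, low-dose CT observes a 2D attenuation image `x*` only through
noisy line integrals

    y = A x* + η,

where `A` is a parallel-beam Radon transform (here 64 views, 512 detector
bins) and `η` is white Gaussian sinogram noise at 30-40 dB SNR.  Filtered
back projection (FBP) of such data is wrecked by streaks and amplified
noise; supervised denoisers fix this but need paired low-dose/normal-dose
training data that is hard and ethically costly to collect.

## The method

Train a denoiser `f_θ` (a U-Net-style encoder-decoder) with a
projection-domain blind-spot loss:

    θ* = argmin_θ  E‖ J( A f_θ(FBP(y_Jc)) − y ) ‖²

- `J` selects one pixel per 4x4 sinogram cell, cycling through all 16
  positions as `iteration mod 16`;
- `y_Jc` is the sinogram with those pixels replaced by their 4-neighbour
  means ("perturbed"), so the network never sees the values it is scored
  against;
- the residual is penalised **only** on the selected pixels, against the
  **unperturbed** sinogram.

Expanding `‖A f_θ − y‖²` shows this objective equals the supervised
projection loss plus the (gradient-free) noise power minus a cross term
that vanishes when the output is independent of the target noise — which is
exactly what the blind spot enforces.  Without it, the identity mapping
satisfies the loss and training collapses onto noisy FBP.  At inference the
sinogram is reconstructed raw: `x̂ = f_θ(FBP(y))`, no perturbation.

The package contains the full desk-scale laboratory: a differentiable
sparse-matrix Radon operator with exact adjoint, Shepp–Logan and
random-ellipse phantom generators, sinogram noise at target SNR, the
blind-spot masking machinery, a numpy U-Net with hand-written backprop,
self-supervised and supervised training loops, classical baselines (FBP,
SART, SART+TV), PSNR/SSIM evaluation, HDF5/TIFF persistence, and a CLI.

## Worked example

Train the compact denoiser self-supervised on twelve 128x128 ellipse
phantoms (64 views, 33 dB) and compare with FBP on held-out phantoms:

```python
import numpy as np
from proj2proj import (
    ProjectionGeometry, RadonTransform, NoiseModel, add_noise_snr,
    random_ellipses_image, DenoiserConfig, build_denoiser,
    TrainConfig, train_proj2proj, reconstruct, fbp_reconstruct, psnr,
)

geom = ProjectionGeometry(image_size=128, n_views=64, n_detectors=128)
proj = RadonTransform(geom)
rng = np.random.default_rng(5)
images = [random_ellipses_image(128, None, rng) for _ in range(22)]
sinos = [add_noise_snr(proj.forward(x), NoiseModel(33.0, seed=100 + i))
         for i, x in enumerate(images)]

cfg = TrainConfig(geometry=geom, learning_rate=3e-3, n_iterations=2000,
                  batch_size=2, seed=0)
denoiser, log = train_proj2proj(sinos[:12], sinos[12:16],
                                build_denoiser(DenoiserConfig.compact(seed=0)), cfg)

for x, y in zip(images[16:], sinos[16:]):
    p_fbp = psnr(x, np.clip(fbp_reconstruct(y, geom), 0, 1))
    p_p2p = psnr(x, np.clip(reconstruct(y, denoiser, geom), 0, 1))
    print(f"FBP {p_fbp:5.2f} dB   proj2proj {p_p2p:5.2f} dB")
```

Output (about five minutes on one CPU core):

```
FBP 19.68 dB   proj2proj 23.99 dB
FBP 19.25 dB   proj2proj 23.54 dB
FBP 16.23 dB   proj2proj 21.49 dB
FBP 16.04 dB   proj2proj 21.55 dB
FBP 19.80 dB   proj2proj 23.05 dB
FBP 23.24 dB   proj2proj 24.55 dB
```

Each line is one held-out phantom: the self-supervised reconstruction beats
its own FBP input by 4.0 dB on average without ever touching a clean image.
(The training loss `log.train_loss` drops about two orders of magnitude
over the run, from ~270 to ~1.6.)

The same experiment, plus SART/SART+TV baselines and CSV/Markdown tables,
is available from the shell:

```sh
proj2proj simulate --out data.h5 --n 10 --size 128 --views 64 --snr-db 33
proj2proj benchmark --config examples/desk.yaml
```

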