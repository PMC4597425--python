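# levysmooth

Reproducible enhancement of latent friction-ridge imagery (and other low-contrast
textured grayscale images): histogram equalization followed by *slow motion*
Lévy-stable fractional-diffusion smoothing, with a machine-readable audit trail
for every run.

## Who this is for

Latent fingerprints left at a scene are low-contrast ridge impressions buried in
clutter — streaks, writing, illumination drift, noise. The common practice of
interactively retouching them (dodge-and-burn style) is hard to document and not
reproducible, which matters when the enhanced image is evidence. `levysmooth`
implements a fully scripted alternative: every step is a deterministic whole-image
operation, every run writes a manifest with cryptographic digests of its inputs
and outputs, and any result can be replayed and verified bit-for-bit.

## The method

1. **Equalize.** Global or tile-based adaptive histogram equalization brings the
   ridge structure into visual range. The value mapping is the min-shift variant
   `v → round(255 · (F(v) − F_min)/(1 − F_min))` with `F` the cumulative intensity
   distribution; the adaptive version computes it per tile and blends the four
   surrounding tile mappings bilinearly.

2. **Smooth progressively.** The enhanced image `f(x, y)` (white ridges), centered
   in an even square of zeros, evolves under the fractional diffusion equation

       w_t = −(−Δ)^p w,   w(x, y, 0) = f(x, y),   0 < p ≤ 1,

   solved spectrally: each DFT coefficient at integer frequency pair (k, l) is
   multiplied by `exp(−t (k² + l²)^p)`. That multiplier is the characteristic
   function of an isotropic Lévy-stable density of index 2p — a Gaussian at
   p = 1, heavy-tailed at the working value p = 0.1. The heavy tail attenuates
   high frequencies far more gently than Gaussian blurring, so background clutter
   fades while ridge detail survives. A default run produces six frames at
   t = 0, 0.1, …, T_max (default T_max = 0.5); the user inspects the suite and
   selects the optimum.

3. **Audit.** The suite, a montage, and a JSON manifest (parameters, embedding
   geometry, SHA-256 digests of every frame) are written to disk. `replay`
   re-runs the manifest against the input and fails loudly on any digest mismatch.

## Worked example

The study images are non-public, so the package ships a seeded synthetic
generator producing latent-print-like fixtures with a known clean ridge channel:

```python
import numpy as np
from levysmooth import (
    SyntheticPrintParams, generate_latent, print_mask, masked_correlation,
    equalize_adaptive, DiffusionParams, smooth_workflow, select_frame, save_suite,
)

params = SyntheticPrintParams(noise_sigma=25.0, seed=1)
latent, clean = generate_latent(params)
mask = print_mask(params)

enhanced = equalize_adaptive(latent)           # 8x8 tile adaptive equalization
suite = smooth_workflow(enhanced, DiffusionParams(p=0.1, t_max=0.5, n_frames=6))
print(f"working array: {suite.frames[0][1].shape}, frame times: {suite.times}")

for i, t in enumerate(suite.times, start=1):
    corr = masked_correlation(select_frame(suite, i), clean, mask)
    print(f"frame {i}  t={t:.1f}  ridge correlation {corr:+.4f}")

manifest = save_suite(suite, "run1", selected_frame=3)
print("frames on disk:", len(manifest.frame_digests))
```

prints

```
working array: (640, 640), frame times: (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
frame 1  t=0.0  ridge correlation +0.6418
frame 2  t=0.1  ridge correlation +0.6565
frame 3  t=0.2  ridge correlation +0.6699
frame 4  t=0.3  ridge correlation +0.6818
frame 5  t=0.4  ridge correlation +0.6921
frame 6  t=0.5  ridge correlation +0.7006
frames on disk: 6
```

The correlation of each frame with the clean ridge channel (inside the print
region) rises as smoothing attenuates the clutter the equalizer amplified —
the quantitative form of "background fades, ridges survive". The same flow is
available from the shell:

```
levysmooth simulate --out-dir syn --noise-sigma 25 --seed 1
levysmooth enhance syn/latent.tiff --out-dir enh --method adaptive
levysmooth smooth enh/sharp.tiff --out-dir run1 --t-max 0.5 --select 5
levysmooth replay run1/manifest.json enh/sharp.tiff
```

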