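# Methods

## Model

The smoothing stage treats the enhanced image `f(x, y)` as initial data for the
linear fractional diffusion problem

    w_t = -(-Δ)^p w,   w(x, y, 0) = f(x, y),   0 < p ≤ 1.

In the Fourier domain the solution is a pure multiplier: the coefficient at
frequency pair (k, l) is scaled by `h(k, l, t) = exp(-t (k² + l²)^p)`. For each
fixed t this is the characteristic function of an isotropic Lévy-stable
probability density of index 2p: the Gaussian at p = 1 (classical heat
equation), a heavy-tailed density with no closed physical-space form, infinite
mean and infinite variance, for p < 1. The operational consequence is the whole
point of the method: at fixed t, `exp(-t r^{2p})` with p = 0.1 decays *far*
more slowly in the frequency radius r than the Gaussian `exp(-t r²)`, so high
spatial frequencies (ridge edges, fine texture) are attenuated gently while the
overall clutter energy still falls. The package asserts this dominance exactly
on the discrete grid: `h_{p=0.1} > h_{p=1}` wherever k² + l² > 1, with equality
at k² + l² ∈ {0, 1}.

### Discretization

Frequencies are *bare integer DFT indices*: an axis of even length 2N carries
k ∈ {−N, …, N−1} (the standard even-length transform's index set; the symmetric
closed range would name one index too many). The continuum factor (2π)^{2p}
that appears in the continuous-space multiplier is deliberately absorbed into
the time variable — under this convention final times T_max ≈ 0.2–0.5 are the
useful smoothing range, and that is the convention all defaults assume.
Rectangular even×even inputs are accepted by the solver itself; the
paper-parity workflow (`smooth_workflow`) first centers the image in an even
square of zeros (floored centering offsets) and crops back after selection.

The solver computes one forward FFT of the input and derives every suite frame
from that single spectrum (multiply, invert, take the real part). By the
semigroup property this equals stepping frame-to-frame but avoids compounding
rounding. The real part — not the magnitude — is taken after inversion: for
nonnegative inputs the imaginary residue is at rounding level, and the real
part preserves linearity.

### Correctness oracles

`dft_oracle_diffuse` re-implements the evolution by explicit direct-summation
DFT matrices (O(N⁴), capped at 32×32) sharing no transform code with the fast
path; the suite asserts agreement to < 1e−10 relative error over randomized
images and parameters. Property tests cover the semigroup composition law
(tolerance 1e−9), DC/mean conservation (1e−10 relative), monotone L2 energy
decay, per-coefficient spectral decay, and the exact Gaussian limit at p = 1.
One caveat discovered and documented in the tests: the *discrete* band-limited
heat kernel at small t is not pointwise nonnegative (truncation ringing); it
becomes effectively a sampled Gaussian — and nonnegative — once the multiplier
has decayed at the band edge (t ≈ 1 on an 8×8 grid).

## Equalization

Both equalizers use the min-shift mapping
`v → round(255 (F(v) − F_min)/(1 − F_min))`, which sends the darkest occupied
level to 0 and uses the full output range; the mapping is monotone, so pixel
ranking is preserved. The adaptive variant partitions the image into a tile
grid (default 8×8, no clip limit), builds one lookup table per tile, and blends
the four surrounding tile-center tables bilinearly per pixel — blockwise
application would cut seams through ridge structure. An optional clip limit
caps each tile histogram at `clip_limit ×` the uniform bin height and
redistributes the excess uniformly (one pass). A constant image (or tile) has
no defined mapping and passes through unchanged — with a warning at image
level, silently as an identity table at tile level. With a single tile the
adaptive path reproduces the global path exactly, which the tests assert as
array equality. These are declared defaults recorded in every manifest; no
claim is made of bit-parity with any particular commercial implementation of
adaptive equalization, whose internals are undocumented.

## Quantization and reproducibility

Working images are float arrays on the nominal [0, 255] scale; values are
quantized — clip to [0, 255], round half away from zero — only at file and
display boundaries. TIFF output is uncompressed, single-strip, 8-bit
grayscale. Digests are SHA-256 over the quantized pixel buffer prefixed by the
image dimensions. Because quantization absorbs floating-point noise well below
half a gray level, replaying a manifest reproduces every frame digest
byte-exactly; `replay_manifest` raises, naming the first offending frame,
otherwise. Display-orientation flips and burned-in caption text are treated as
presentation, not data: captions live in filenames and the manifest, where
they are verifiable, rather than in pixels, where they are not.

## Synthetic fixtures

Real latent prints come from non-public forensic collections, so tests run on
a seeded generator that emulates their structure: a smooth random orientation
field (coarse angles one node per `orientation_scale` = 200 px, bilinear
upsampling, per-pixel angle gradient provably ≤ π/orientation_scale) drives an
oriented stripe pattern of period 10 px whose phase integrates the local wave
vector (no phase tearing); the pattern is masked to an ellipse, composited
over background level 120 with ±25 gray-level illumination drift, 4 bright
streaks, one block of text-like bars, Gaussian noise (σ = 15 by default, 25 in
the smoothing-benefit experiment), and an optional disk-kernel smudge blur.
All randomness flows from one seed through a single generator. The clean
masked ridge term is returned as ground truth so fidelity is measured by plain
masked Pearson correlation, no registration needed.

What the fixture does *not* emulate: minutiae, pores, elastic skin distortion,
overlapping prints, sensor-specific noise. Passing tests therefore demonstrate
that the pipeline behaves as designed on oriented-texture-in-clutter imagery;
they do not certify performance on casework images, which is an operator
judgment the audit trail is designed to support, not replace.

### Measured behavior (recomputed by the test suite and acceptance script)

On the seed-1 fixture with noise σ = 25, global equalization followed by
heavy-tailed smoothing raises the masked ridge correlation from 0.615 at t = 0
to a maximum of 0.621 at t = 0.2, while Gaussian smoothing at the matched
final time t = 0.5 destroys the ridge band entirely (correlation ≈ 0). These
numbers are pinned as regression values computed once from the package itself;
they are properties of the synthetic conditions, not claims about any
particular real print.

## Numerical and design choices

- **Frame schedule**: t_m = (m−1) T_max/(n_frames−1), m = 1…n_frames; default
  six frames, T_max = 0.5, p = 0.1. Frame 1 is always the untouched input.
- **Padding**: the solver requires even dimensions; `smooth_workflow` pads to
  the smallest even square that fits unless told otherwise. Padding with zeros
  (not reflection) matches the reference workflow and keeps the pixel sum
  exact; the induced boundary transient stays inside the pad margin for the
  short times used.
- **Centering parity**: offsets use floor division for odd differences; the
  choice is recorded in the manifest via the embed record.
- **Rounding**: one rule everywhere (half away from zero after clipping).
- **Degenerate inputs**: constant images pass through equalization unchanged
  with a warning; t = 0 returns the input array exactly; odd-dimensioned
  inputs are rejected with a pointer to padding rather than silently resized.
- **Interfaces**: the interactive select-a-frame loop of the original
  workflow is replaced by flags and re-invocation; exploring several T_max
  values means several runs, each with its own manifest — better audit
  semantics than a UI. Acceptance-scale problem sizes (8×8 oracle images,
  64-point multiplier grids, the 480×640 default fixture padded to 640²)
  were chosen so the whole verification sweep runs in seconds.

## Known limitations

- The smoothing is linear and isotropic; it will not sharpen, deblur, or
  adapt to local ridge frequency.
- Equalization parity with any specific legacy implementation is a non-goal;
  outputs differ at pixel level from such tools by design.
- Byte-exact replay is guaranteed on a single platform/library stack; across
  stacks with different FFT rounding, differences are absorbed by quantization
  in practice but are not formally certified.
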