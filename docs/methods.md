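# Methods

This note documents the model, the numerical choices, and the synthetic
data used by the test suite, including what those tests do and do not show
about real data.

## Forward model

A 2D-multislice acquisition excites and reads out one slab at a time, so
the through-plane direction is characterized entirely in the image domain
by the slice-selection profile `h`, a low-pass kernel whose FWHM is the
slice thickness `T`. The observed volume is modeled as

    y = (x * h) ↓ r,    r = s / s*,  s = T + G,

with `x` the unobserved isotropic volume, `G` the slice gap, `s` the
center-to-center slice separation and `s*` the target (in-plane)
separation. The gap is represented purely by FWHM(h) < s; taps are never
zeroed. Two discretization decisions are ours (the convention is not
forced by the model):

- **Profile normalization** to unit sum, so blurring preserves mean
  intensity; all profile constructors, tap-table loading, and the
  adversarial estimate enforce it.
- **Convolution boundary** is edge replication, which avoids darkened
  volume ends under unit-sum taps.

Degradation is always blur-then-subsample, and the subsampling grid is the
FOV-aware grid below, so a simulated LR volume shares its FOV center with
its HR source exactly.

## FOV-aware resampling

Regridding a discrete signal to a new spacing cannot simultaneously keep
(1) the FOV center, (2) the requested spacing, and (3) the boundary sample
positions, because the output count must be an integer. This package keeps
(1) and (2): with input count `N` (spacing normalized to 1) and requested
spacing `d`, the output has `N' = ⌊N/d⌉` samples with the first at
`c − (d/2)(N'−1)`, where `c = (N−1)/2` is the input FOV center. The
boundary-anchored alternative (keeps (1) and (3), adjusts the spacing to
`(N−1)/(N'−1)`) is implemented for comparison and ablation only.

Numerical choices:

- **Rounding** `⌊·⌉` is round-half-away-from-zero, centralized in
  `grids.round_half_away` and used for every count computation in the
  package (resampling, slice counts, patch sizes).
- **Interpolant** is an interpolating cubic B-spline (coefficients from
  the banded spline system) with a *natural* boundary — end coefficients
  linearly extrapolated — so constants and linear ramps are reproduced to
  machine precision through the ends; evaluation positions outside the
  sample support are clamped (edge replication). Linear and nearest
  kernels exist for tests.
- Every resampling operation is materialized as a dense `(N', N)` matrix.
  This is what makes exact backpropagation through the network head
  possible (the adjoint is the transpose) and it is cached per
  `(N, d, kernel)`.
- **No anti-alias prefilter** inside the resampler: in this pipeline
  downsampling is always preceded by a profile blur, or follows integer
  sub-pixel upsampling with a residual factor above 1/2, so a prefilter
  would double-filter.

## Relative slice-profile estimation

The profile needed for self-training is *relative*: the kernel that makes
degraded in-plane patches indistinguishable in distribution from observed
through-plane patches. It is estimated adversarially:

- Generator: fixed 16-dim latent → Dense(64) → ReLU → Dense(21) →
  tanh-bounded logits → softmax. The softmax guarantees nonnegative
  unit-sum taps; the logit bound (±4) keeps gradients alive for every tap
  so the estimate can recover from transient collapse.
- Fakes: in-plane windows blurred by the candidate taps (valid
  convolution) and FOV-aware downsampled by `r` to 8×8. Reals: 8×8
  through-plane windows. **Every patch is standardized to zero mean and
  unit variance before the discriminator.** This is load-bearing: blurring
  lowers patch variance, and a discriminator allowed to see raw
  intensities keys on that variance difference, which drives the estimate
  toward a near-delta kernel. Standardization forces the game onto
  correlation structure, where the optimum sits at the true width (we
  verified this with discriminator-only sweeps against fixed candidate
  widths).
- Discriminator: two 3×3 conv + ReLU + 2×2 average-pool stages and a
  dense head; least-squares GAN loss; alternating Adam updates
  (generator 3e-4, discriminator 5e-4).
- Regularization: a second-difference smoothness penalty at 1e-3 (at 1e-2
  its widening pressure overwhelms the data signal — on an isotropic
  input, where the correct answer is a delta, the estimate drifted to
  FWHM 15), a quartic edge-mass penalty (profiles are compact; an 8-sample
  discriminator window cannot see ghosts 10 taps from center), and a
  center-of-mass penalty since the translation of `h` is not identifiable.
- Initialization at the Gaussian fallback profile (FWHM = slice
  separation, the no-gap assumption) rather than near-uniform; the
  adversarial phase then refines the width. Taps are averaged over the
  final 25% of the 1500 iterations (the last iterate of an adversarial
  game is noisy) and the center of mass is re-shifted to the middle tap.

With the default configuration the estimate is bit-reproducible on CPU
for a fixed seed. On the 64³ phantom degraded with known Gaussian
profiles, recovery is within 25% of FWHM 3/4/5 mm with the ordering
preserved (the acceptance suite recomputes this). Symmetry is not
enforced; real profiles may be asymmetric.

## SR network and self-training

Wide-activation residual design: conv 1→C, `n_blocks` blocks of
(conv C→4C, ReLU, conv 4C→C, identity skip), conv C→⌈r⌉. Block internals
(3×3 kernels, 4× expansion, no weight normalization) are this package's
defaults — the wide-activation family leaves them free. The noninteger
scale `r` is decomposed `r = ⌈r⌉ · (r/⌈r⌉)`: a 1-D sub-pixel shuffle
along the through-plane axis realizes ⌈r⌉, then FOV-aware downsampling by
`r/⌈r⌉` lands on the target grid (`N_out = ⌊N·r⌉`); when `r` is integer
the downsampling step is skipped bit-exactly. A global skip adds the
FOV-aware cubic upsampling of the input, and the last trunk convolution is
zero-initialized, so at initialization the network *is* the cubic
upsampler — training can only improve on that anchor, and the ablation
"interp head" variant replaces shuffle+downsample by direct resampling of
the trunk output.

Training pairs come from the volume's own in-plane slices: HR windows of
`⌊8r⌉×8` (same rounding operator), degraded by the estimated profile and
FOV-aware downsampled to 8×8. The degradation axis is the window's first
axis; random transposition and flips supply both in-plane directions.
Sampling is uniform over valid positions. Optimization is Adam at 1e-3
with a one-cycle schedule (warmup 30%, div 25, final div 1e4) on MSE.
Intensities are min-max normalized to [0, 1] with the exact inverse
applied after inference.

Everything runs in plain numpy with hand-written backpropagation
(`eclare.nn`); there is no framework dependency. Network arithmetic is
float32 by default (the loop is CPU compute-bound; float32 is ~2.4×
faster) with float64 available via `SRModelConfig.dtype` where bit-exact
agreement with the float64 resampling operators is asserted. Training is
deterministic for a fixed seed.

Presets: `paper` is the full-scale setting (16 blocks × 256 channels,
1,000,000 patches, batch 128) — a GPU-scale budget retained for
completeness; `desk` (4 blocks × 32 channels, 10,000 patches, batch 32)
is the CPU-scale default used by the examples and tests, sized so that a
per-volume fit takes about a minute on one core.

## Inference and evaluation

The 2-D network is fully convolutional in-plane, so it is applied to
full-width slices despite being trained on 8-wide patches. Both
orientations containing the through-plane axis are processed slice-wise
(batched; results independent of batch size) and averaged voxel-wise.
The output through-plane count is `⌊N_LR·r⌉`, which can differ from the
original HR count by a sample; since both grids are FOV-centered, they
are then offset by half a sample. Evaluation therefore regrids the SR
volume onto the reference grid through world coordinates
(`eclare.regrid_like`) before computing metrics. PSNR uses
`20·log10(range/RMSE)` with the reference max−min as default range; SSIM
is the scikit-image implementation (3-D, 7-voxel window by default, with
a slice-wise option). A binary Dice utility exists for phantom-lesion
overlap checks only.

## Synthetic phantoms

`PhantomSpec`/`make_phantom` generate isotropic volumes from analytic
shapes on the integer grid with a seeded generator (bit-reproducible
across platforms): a smooth intensity gradient, random ellipsoids, nested
spherical shells, obliquely oriented rods, optional bright spherical
"lesions", band-limited texture (smoothed white noise), and optional
additive noise. The rods and shells are deliberately oblique so that
through-plane degradation produces visible aliasing — axis-aligned
content would understate what super-resolution has to recover. The
lesion preset emulates bright-blob pathology qualitatively, with no claim
of radiological realism.

What passing tests on these phantoms show: the grid laws, the forward
model, pairing consistency and the training/inference machinery are
correct, and the full configuration beats both its own baseline ablation
and cubic interpolation under a known, exactly simulated degradation.
What they do not show: performance under MR noise, bias fields, motion,
real slice-excitation imperfections, or anatomy-specific texture; no
contrast physics is modeled. One phantom-specific caveat found during
development: thick-slab averaging smears oblique structures laterally, so
the *in-plane* statistics of a simulated LR phantom are themselves
slightly blurred; this is physically faithful (real thick-slice volumes
have the same property) but it makes the relative profile genuinely
narrower than the true excitation profile when oblique content dominates
— patch standardization in the estimator largely removes the resulting
bias.

## Known limitations

- Per-volume training from scratch: minutes per volume on CPU at desk
  scale; no pretraining or fine-tuning across volumes.
- Axis-aligned geometry only; oblique acquisitions are accepted but only
  axis-wise spacing/origin bookkeeping is tracked.
- The dense-matrix resampler is designed for axis lengths up to a few
  thousand samples; it is not a general N-D regridder.
- The profile estimator needs sufficient in-plane extent
  (`⌊8r⌉ + 20` samples) and at least 8 slices; below that the Gaussian
  fallback is the practical choice.
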