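# eclare-sr

Self-supervised through-plane super-resolution for anisotropic 2D-multislice
MR volumes, after the ECLARE method (Efficient Cross-planar Learning for
Anisotropic Resolution Enhancement).

Clinical MR volumes are often acquired as stacks of thick 2-D slices:
in-plane resolution is sub-millimeter while slices are 3–8 mm thick, often
with a gap between them. Algorithms designed for isotropic volumes degrade
badly on such data. This package restores through-plane resolution using
**only the volume itself** — no external training data — which makes it
applicable to any contrast, anatomy, or resolution.

## Who this is for

Researchers processing anisotropic 2D-acquired MRI (neuroimaging pipelines,
lesion studies, retrospective clinical data) who need an isotropic volume
and want the reconstruction constrained by an explicit acquisition model
rather than a population prior.

## The model

A 2D-multislice acquisition is modeled as blurring of the unobserved
isotropic volume `x` by the slice-selection profile `h` along the slice
axis, followed by subsampling:

```
y = (x * h) ↓ r ,     r = s / s*
```

where `s` is the low-resolution slice separation (thickness `T` + gap `G`,
written `T∥G`), `s*` the target high-resolution separation, and the FWHM of
`h` is the slice thickness. If FWHM(h) < s the model captures a slice gap.
The method has four parts:

1. **Relative slice-profile estimation.** A 21-tap profile `h̃` is estimated
   adversarially from the volume: a generator proposes taps, in-plane
   patches degraded by `h̃` are compared by a discriminator against real
   through-plane patches (least-squares GAN). A Gaussian fallback with
   FWHM = s is available when estimation is not wanted.
2. **FOV-aware resampling.** All regridding keeps the requested sample
   spacing *exact* and the field-of-view center *fixed* (an `N`-sample
   signal resamples to `⌊N/d⌉` samples placed symmetrically about the
   original FOV center), compromising only boundary sample positions.
3. **Self-training.** HR patches of size `⌊8r⌉×8` are cut from the volume's
   own in-plane slices; degrading them with `h̃` plus FOV-aware
   downsampling by `r` yields paired 8×8 LR inputs. A wide-activation
   residual network (WDSR-style; default 16 blocks × 256 channels, desk
   preset 4 × 32) is trained from scratch with Adam + one-cycle on MSE.
   The noninteger scale is handled by the head as `r = ⌈r⌉ · (r/⌈r⌉)`:
   1-D sub-pixel shuffle by `⌈r⌉`, then FOV-aware downsampling by
   `r/⌈r⌉`, plus a global skip of the FOV-aware cubic upsampled input.
4. **Dual-axis inference.** The 2-D network super-resolves all slices of
   both orientations containing the through-plane axis; the two volumes
   are averaged.

The network and its training loop are implemented directly in numpy with
hand-written backpropagation (see `eclare.nn`), so the package has no deep
learning framework dependency and is bit-reproducible on CPU for a fixed
seed.

## Worked example

Everything below runs on a synthetic phantom — no data download.

```bash
eclare make-phantom --out hr.nii.gz --size 64 --seed 1
eclare simulate hr.nii.gz --out lr.nii.gz --thickness 4 --gap 1
eclare run lr.nii.gz --out sr.nii.gz --profile espreso --preset desk --seed 0
eclare evaluate hr.nii.gz sr.nii.gz
```

Output of the four commands (desk preset, one CPU, ~90 s for `run`):

```
{"out": "hr.nii.gz", "shape": [64, 64, 64]}
{"out": "lr.nii.gz", "ratio": 5.0, "lr_slices": 13}
{"out": "sr.nii.gz", "ratio": 5.0, "profile_fwhm_mm": 4.216, "final_loss": 0.00088}
{"psnr": 29.643, "ssim": 0.845}
```

Reading these numbers: the 4∥1 simulation (4 mm slices, 1 mm gap) gives an
anisotropy ratio r = 5 and 13 slices from 64; the adversarial estimate
recovers a profile of FWHM ≈ 4.2 mm (the simulation used 4.0 mm); the
super-resolved volume scores PSNR 29.64 dB / SSIM 0.845 against the
ground-truth phantom, versus 29.14 dB / 0.814 for FOV-aware cubic
interpolation of the same input (`eclare evaluate` after
`eclare.resample_axis`).

The same pipeline as a library, scikit-learn style:

```python
import eclare as e

hr, lr, geom = e.make_pair(e.PhantomSpec(shape=(64, 64, 64), seed=1), 4.0, 1.0)
sr = e.EclareSuperResolver(preset="desk", seed=0).fit(lr, geometry=geom).transform(lr)
print(e.psnr(hr, e.regrid_like(sr, hr)))
```

`EclareSuperResolver` exposes the three ablation switches from the method's
component analysis: `profile=` ("estimate" / "fallback" / taps),
`resample_convention=` ("fov" / "boundary") and `head=` ("shuffle" /
"interp"); `eclare.run_ablation` evaluates the full 2³ grid.

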