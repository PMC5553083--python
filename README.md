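# weakdecon

Simulation and prefiltered deconvolution of **very weak photon-counting
confocal signals**.

When live-cell 4D confocal stacks are captured gently enough to avoid
photodamage, a pixel inside a labelled structure often records only one or
two photons. Classic maximum-likelihood deconvolution can then erase
structures that are plainly visible in the raw data. Prefiltering each
optical section with a small Gaussian blur (σ ≈ 0.75–1.0 px) before
deconvolution spreads the isolated photon events over neighbouring pixels
and preserves the structures, while leaving their integrated intensities
essentially unchanged.

`weakdecon` is a synthetic test bed for that procedure, aimed at microscopy
facility staff and image-analysis developers who want to validate a
deconvolution pipeline at photon-counting signal levels:

* **Optics** — scalar Born & Wolf PSFs
  `h(r,z) = |∫₀¹ J₀(k·(NA/n)·r·ρ)·e^{−i k z ρ² NA²/(2n)} ρ dρ|²` and the
  effective confocal PSF as the excitation × emission product.
* **Simulation** — an 8×8 lattice of point emitters on a 200×200×40 grid
  (80×80×250 nm voxels), imaged by linear FFT convolution, normalized to a
  peak expectation of 1 photon (~17 photons per object in total), optional
  0.01 photons/voxel background, Poisson sampling, and 8-bit encoding with
  4 photons at code 255.
* **Prefilter** — flux-preserving truncated-Gaussian blur (2D per slice or
  3D), with the ×256 16-bit promotion used for real photon-counting data.
* **Deconvolution** — Richardson–Lucy EM for `d ~ Poisson(Hx + b)` with the
  background inside the forward model, fixed 40 iterations, recorded
  log-likelihood trace and flux correction.
* **Quantification** — average projection, 20×20-px ROI integrated
  densities at the known emitter positions, and a 5σ preserved-object count
  against lattice-midpoint background windows.

## Worked example

```python
from weakdecon import (BlurConfig, DeconvConfig, ExperimentConfig, SimConfig,
                       run_experiment, compare_reports)

cfg = ExperimentConfig(
    sim=SimConfig(seed=1),                     # noise-free default lattice
    blur=BlurConfig(sigma=0.75, mode="2d"),
    deconv=DeconvConfig(iterations=40, background=0.0),
    pipelines=("raw", "blur_decon"),
)
res = run_experiment(cfg)
for arm, r in res.items():
    print(arm, r.report.n_preserved, "of", len(r.report.per_object))
print("median density ratio:",
      round(compare_reports(res["raw"].report, res["blur_decon"].report)["median_ratio"], 3))
```

prints

```
raw 64 of 64
blur_decon 64 of 64
median density ratio: 0.992
```

All 64 simulated objects (~10–25 detected photons each) survive the blur +
40-iteration Richardson–Lucy pipeline, and their integrated densities stay
within ~1% of the unprocessed stack's — the prefilter preserves weak signals
without inflating or deflating them. With 0.01 photons/voxel of added
background (`SimConfig(background=0.01)`, 3D blur, manual deconvolution
background of 0.05 photons/voxel) the same pipeline removes most of the
noise and typically preserves 62–64 of the 64 objects; see `docs/methods.md`
on choosing the background level for noisy data and on why full preservation
is marginal at these photon counts for an unregularized deconvolver.

The same steps are available from the shell:

```bash
weakdecon simulate --seed 1 --out stack.tif
weakdecon blur --sigma 0.75 --mode 2d stack.tif blurred.tif
weakdecon psf --out psf.tif
weakdecon deconvolve --iterations 40 --background 0 --psf psf.tif blurred.tif estimate.tif
weakdecon project estimate.tif projection.tif
weakdecon quantify --layout stack.tif.layout.json projection.tif report.csv
# or all arms at once:
weakdecon experiment --seed 1 --outdir results/
```

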