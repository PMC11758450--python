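# prfbias

Resampling-induced coverage bias in population receptive field (pRF)
mapping, quantified on synthetic retinotopic phantoms.

## The problem

pRF mapping fits each fMRI voxel (or surface vertex) with an isotropic
2-D Gaussian in visual space — center (x, y), size σ — from its response
to a traveling bar aperture.  Group results are often summarized as
*visual-field coverage maps*: the average, at every visual-field location,
of the fitted unit-height Gaussians of all units passing a
variance-explained (ve) threshold.  The same data analyzed in volume space
versus projected to the cortical surface yield systematically different
coverage: the surface analysis shows more coverage in the central visual
field.  Because cortical magnification

    M(E) = A / (E + E2),   A = M0·E2,   E(d) = E2·(exp(d / A) − 1)

compresses the fovea into little cortex, grid interpolation
(volume→surface projection, or 2 mm→1 mm reslicing) interacts with the
exponential cortical location function E(d), with noise averaging, and
with ve thresholding to produce a foveal bias that is a property of the
pipeline, not of the brain.

`prfbias` reproduces and dissects this effect end-to-end on *phantoms* —
flat cortical slabs with exactly known ground-truth pRFs — for
methodologists who need to know how much of a retinotopy result is
analysis artifact.  It provides:

- `prfbias.stimulus` — binary bar-aperture sequences (8 directions, 7.8°
  field, 1.95° bar, 135 frames);
- `prfbias.clf` — the cortical location function / magnification model,
  the moving-ring empirical CMF estimator, and the hyperbolic model fit;
- `prfbias.phantom` — slab phantoms, the Gaussian-pRF × aperture × HRF
  forward model, controlled-CNR noise, artificial-subject populations;
- `prfbias.fitting` — coarse-to-fine single-Gaussian pRF estimation,
  vectorized over whole datasets;
- `prfbias.resampling` — volumetric upsampling, emulated vol2surf with
  cortical-depth averaging, subsampling, noiseless substitution,
  parameter projection;
- `prfbias.covstats` — coverage maps, paired Cohen's d maps, subject
  bootstrap, matched thresholds, fovea/periphery summaries;
- `prfbias.experiments` — the end-to-end experiments, fully seeded and
  byte-reproducible, plus a thin `prfbias` CLI.

## Worked example

Simulate ten phantom subjects, fit pRFs in the volume, project the time
series to an emulated surface and refit, then compare coverage:

```python
import numpy as np
from prfbias.experiments import ExperimentConfig, run_volume_vs_surface

rep = run_volume_vs_surface(ExperimentConfig(master_seed=0, n_runs=2))
print(f"vertex/voxel ratio   {rep['vertex_voxel_ratio']:.2f}")
print(f"mean d, fovea <1deg  {rep['mean_d_fovea']:+.2f}")
print(f"mean d, beyond 4deg  {rep['mean_d_periphery']:+.2f}")
```

prints

```
vertex/voxel ratio   4.10
mean d, fovea <1deg  +2.20
mean d, beyond 4deg  +2.95
```

— the surface mesh holds ≈4.1× more units than the 2 mm volume, and the
surface condition's coverage exceeds the volume's with a strong foveal
core (paired Cohen's d +2.2 averaged over the central 1°).  The noiseless
variant (`run_experiment("noiseless", ...)`) shows the same foveal pattern
with no noise at all, isolating the interpolation mechanism, while
controls (volume vs itself, surface vs its own random subsample, zero
CNR gap) are null.  Recovering the magnification model from fitted phantom
data closes the loop:

```python
from prfbias.experiments import run_cmf_fit
rep = run_cmf_fit(ExperimentConfig(experiment="cmf_fit", n_subjects=30,
                                   cnr=np.inf, master_seed=0))
print(rep["recovered"])   # {'M0': 13.99..., 'E2': 1.437..., 'A': 20.1...}
```

recovering the cohort's generating foveal magnification (14.15 mm/deg for
these 30 drawn subjects) within ~1% from the moving-ring empirical CMF.

The same experiments are available from the shell:

```bash
prfbias experiment volume_vs_surface --seed 0 --out results/
prfbias experiment cmf_fit --seed 0 --out results/ --figures
```

See `docs/methods.md` for the models, the generator's assumptions, and
what the phantom results do and do not imply about real data.

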