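# Methods

`prfbias` studies a measurement artifact of population receptive field
(pRF) mapping: when volumetric fMRI data are resampled — projected onto a
cortical surface mesh, or resliced to a finer voxel grid — the resulting
visual-field coverage maps acquire a systematic foveal bias.  Because the
bias concerns the *analysis pipeline* rather than the brain, it can be
studied exactly on synthetic data where the ground truth is known.  This
note documents the models, the generator, the estimators, and the numerical
choices.

## The cortical location function and magnification model

Visual cortex magnifies the fovea: the linear cortical magnification factor
M(E) (mm of cortex per degree of visual field at eccentricity E) is modeled
as the hyperbolic function

    M(E) = A / (E + E2),        A = M0 · E2   [mm]

with `M0` the foveal magnification (mm/deg) and `E2` the eccentricity at
which inverse magnification doubles.  Integrating M from the occipital pole
gives the exponential *cortical location function* mapping cortical
distance d (mm) to eccentricity:

    E(d) = E2 · (exp(d / (M0·E2)) − 1)

Both directions, their consistency (d(E) = ∫₀ᴱ M), and the analytic
inverse are implemented in `prfbias.clf` and verified against quadrature to
1e−6.  Defaults follow V1-like values M0 = 14 mm/deg, E2 = 1.4°.

## The phantom

`prfbias.phantom` realizes early visual cortex as a *flat slab*: a regular
voxel grid whose axes are cortical distance, polar angle, and cortical
depth.  All voxels in a depth column share one ground-truth pRF:
eccentricity from the location function, polar angle linear along axis 1,
size σ = σ₀ + 0.1·E with σ₀ = 0.5°.  A folded mesh is deliberately
avoided: the mechanisms under study (the nonlinearity of E(d) composed
with grid interpolation) are geometry-agnostic, and the flat slab makes
ground truth and vertex placement exact and testable.

Geometry defaults: 2 mm isotropic voxels, 19 distance steps (0 to the
7.8°-field edge at 36.9 mm), 20 polar steps tiling 180° per hemifield
(cell-centered, so two mirrored hemifields tile the full field with no
overlap and no gap), 3 depth voxels.  Each column also carries the exact
cortical area it represents under the isotropic magnification model
(closed-form integral of M²·E over its visual patch), which feeds the
empirical CMF estimator.

**BOLD forward model.**  The stimulus is the standard traveling-bar
aperture: 1.95°-wide bar, 7.8° circular field, 8 directions × 16 steps
plus 7 blank frames = 135 frames at TR 1.883 s.  A unit-height isotropic
Gaussian pRF integrates the binary aperture per frame; the neural drive is
convolved with a canonical double-gamma HRF (peak 6 s, undershoot 16 s,
ratio 1/6 — unspecified by the pipeline being emulated, so the standard
kernel is used).

**Noise.**  `add_noise` implements per-series CNR = std(signal)/std(noise)
with i.i.d. Gaussian noise (optional AR(1)).  `simulate_subject` defaults
to a single slab-wide noise floor (sd = mean signal sd across columns
divided by the nominal CNR): scanner thermal noise is flat across voxels
while response amplitude varies with pRF size, so small foveal pRFs
genuinely have lower CNR.  This choice matters — normalizing CNR per voxel
makes every voxel equally reliable and suppresses the threshold-selection
effects that drive part of the resampling bias.

**Subjects.**  Artificial subjects differ by a sub-voxel jitter of the
slab placement and a lognormal scatter (CV 8%) of M0, E2 and σ₀,
emulating between-subject anatomical variability.  Populations for the
CNR/size simulations draw pRF centers from an isotropic 2-D Gaussian about
fixation (spread 3°, constant σ = 1°).

## pRF fitting

`prfbias.fitting` estimates the single-Gaussian model coarse-to-fine.
Gain and baseline are profiled out in closed form, so candidate quality is
the squared correlation of demeaned data with the demeaned prediction
(negative gains are rejected).  The coarse stage scans a center lattice
(default 0.5° steps over 1.1× the field radius) crossed with log-spaced σ
(0.25–4°, 12 levels); exact ties are broken toward smaller σ, then smaller
eccentricity.  The fine stage refines (x, y, log σ) with Nelder-Mead run
*batched*: one vectorized optimizer advances all units of a dataset
simultaneously, freezing converged rows.  This makes the ~10⁵–10⁶ fits of
the experiment suite feasible on one core (≈1 ms per unit) and is
deterministic.  Noiseless phantoms are recovered to ≈10⁻⁴ deg; white-noise
series stay below 20% variance explained in >95% of trials at the 135-frame
run length.

## Resampling operations

* `upsample_volume` — reslice each frame to a finer isotropic grid
  (trilinear or nearest), source and target sharing the first voxel
  center.  Trilinear reproduces affine fields and node values exactly.
* `project_to_surface` — emulated vol2surf: a vertex lattice (default
  0.95 mm, giving the (2/0.95)² ≈ 4.4 vertex/voxel density ratio of
  typical FreeSurfer meshes against 2 mm data) samples the volume at six
  cortical depth fractions (0, 0.2, …, 1.0) and averages across depth.
* `subsample_units` — seeded uniform subset without replacement.
* `substitute_noiseless` — replace each voxel's series by the model series
  of its fit (failed fits zeroed and flagged); refitting recovers the
  substituting parameters, the operational definition of "noiseless data".
* `project_parameters` — interpolate fitted parameter maps (not time
  series) to the vertex lattice with the same depth-averaging scheme.

## Coverage statistics

A coverage map places a unit-height Gaussian at each above-threshold pRF
and averages over pRFs on a square grid over [−R, R]² (default 64×64 for
experiments, 128×128 for reports).  Conditions are compared per pixel with
paired Cohen's d (n−1 sd); |d| is clipped at 10 and pixels with
identically zero differences get d = 0, since vanishing difference
variance otherwise yields unbounded values.  Group maps pool pairs across
subjects and runs and are bootstrapped by resampling subjects (50
iterations); a per-subject pairing mode (d across runs, bootstrap of
subject maps) is available but heavy-tailed at 4 runs (t₃) and therefore
not the default.  `matched_threshold` returns the surface ve threshold
masking the same unit fraction as a base volumetric threshold, by
empirical quantile matching.

Region summaries average d over the foveal disc (default E < 1°, the
foveal pRF-size scale where the positive core of every resampling effect
concentrates) and the periphery (E > 4°), excluding pixels outside the
inscribed circle.

## Experiments and their design conditions

All experiments derive every seed from a master seed (reports are
byte-reproducible) and run at a desk scale chosen for minutes-scale
turnaround; problem sizes are part of each report.

* **volume_vs_surface** (10 subjects × 4 runs, CNR 2): fit volume, project
  time series to the surface, refit, compare coverage.  Surface minus
  volume is foveally positive; the vertex/voxel ratio (≈4.1 with lattice
  edge effects) and the matched surface threshold are reported.
  The noiseless variant (CNR ∞, one run, 50% ve threshold) isolates the
  interpolation mechanism: trilinear mixing of neighboring columns
  broadens fitted σ (nearest-neighbor projection does not), and the foveal
  pattern persists without any noise.
* **cnr_sweep** (10 × 4, 500 pRFs/population): condition pairs (∞ vs ∞),
  (4 vs ∞), (2 vs ∞).  The zero-gap level is an exact identical-data null
  (d ≡ 0); increasing gaps produce increasing foveal d and negative
  peripheral d — noisy fits scatter peripherally, clean fits do not.
* **size_sweep**: same centers with σ scaled by (1 + increment),
  increments 0/25/50/100% — a paired size manipulation with an exact null
  at zero.  Coverage rises globally with far weaker fovea/periphery
  contrast than the CNR effect.
* **equal_n / surface_self_subsample** (noiseless products): subsampling
  the surface to the volume's unit count leaves the foveal bias intact
  (it is not a unit-count effect); the surface against its own subsamples
  (12 draws/subject) is a null within |d| < 0.1.
* **upsample_2to1** (8 subjects × 1 run, mean CNR 1): 2→1 mm trilinear
  reslice, refit, compare.  Run at CNR 1 because the peripheral coverage
  loss is a noise-averaging/selection effect: interpolated voxels average
  noise away and recover weak (foveal, small-σ) responses that the
  original resolution loses, while the original's noisy peripheral scatter
  is not replicated; at CNR 2 the σ-broadening of interpolation dominates
  and lifts coverage everywhere.
* **cmf_fit**: fit phantom volumes, attach exact per-column areas
  (divided by cohort size so the pooled cohort covers each annulus once),
  moving-ring areal CMF (1° rings sliding by 0.25°, units filtered at
  ve ≥ 10% and E ≤ 9°, ring centers capped at the phantom's mapped range,
  sample eccentricity = area-weighted ring mean), square root, fit Eq. M(E).
  Noiseless recovery uses 30 subjects: a single 2-mm slab quantizes ring
  sums by ±25%, and jittered subjects dephase this to ≈1% median M0 error;
  with noise (CNR 4, 10 subjects) the scatter itself smooths the
  quantization and recovery is well under 10%.

## What the phantom does and does not show

Passing tests demonstrate that the *pipeline operations alone* — trilinear
projection/reslicing composed with cortical magnification, thresholding,
and noise — generate a foveal coverage bias on data with perfectly known,
bias-free ground truth, and that controls (identical conditions,
self-subsampling, zero gaps) are null.  The phantom does not contain
folded cortical geometry, non-retinotopic or partial-volume voxels,
physiological noise, or realistic ve distributions; consequently the
masked-fraction magnitudes of real cohorts (and effect magnitudes
generally) are not reproduced quantitatively — only the signs, orderings,
and mechanisms.  Cohen's d values on nearly-deterministic phantom
differences saturate at the ±10 cap and should be read as "consistent",
not as physiologically meaningful magnitudes.

## Numerical choices

* Stimulus rendered at 24×24 px for experiments (0.65°/px; forward and
  inverse models share the rendering, so fits are self-consistent) and
  48×48 px for precision recovery checks; a warning flags σ below half a
  pixel.
* Batched Nelder-Mead: standard coefficients (1, 2, 0.5, 0.5), 60–120
  iterations, xatol 5e−3–1e−3; rows whose simplex collapses are frozen.
* Interpolation via `scipy.ndimage.map_coordinates` (order 1/0, edge
  clamped); reslicing targets never extend beyond the source extent.
* Degenerate inputs: constant time series are errors in `fit_prf`/
  `add_noise` and flagged (not fatal) in `fit_dataset`; empty moving-ring
  windows are recorded and omitted; empty coverage (no unit above
  threshold) is an error.
* Master seed 0 throughout the test suite; seeds derived per stage via
  `SeedSequence(master, spawn_key=crc32(path))`, all below 2³¹.

## Known limitations

* The moving-ring estimator on 2-mm-quantized single subjects has a ~1–3%
  seed-dependent M0 error floor; denser sampling (more subjects, finer
  voxels) reduces it.
* The phantom's homogeneous noise floor makes ve thresholding either
  bite everywhere or nowhere as CNR varies; real data with heterogeneous
  voxel quality sit between the regimes exercised here.
* Hemifields are simulated as independent mirror slabs; no
  vertical-meridian continuity or ipsilateral overlap is modeled.
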