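"""End-to-end phantom experiments quantifying resampling-induced coverage bias.

Each ``run_*`` function simulates phantom subjects, applies one resampling
manipulation, fits pRFs on both sides, and reduces the paired coverage
difference to an effect-size report:

- volume vs. emulated surface projection (with a noiseless variant),
- CNR-gap and pRF-size sweeps on artificial pRF populations,
- equal-N subsampling controls,
- 2 mm -> 1 mm volumetric upsampling,
- cortical magnification recovery (moving ring + hyperbolic fit).

Every stochastic stage draws its seed deterministically from the master
seed, so a (config, seed) pair reproduces results exactly.  Group effect
maps pool paired differences over subjects and runs (Cohen's d across all
pairs) and bootstrap the pooling over subjects; a per-subject pairing mode
(d across runs within subject, then bootstrap across subjects) is available
via ``pairing="subject_runs"``.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import covstats
from .clf import CorticalMapping, estimate_cmf_moving_ring, fit_cmf
from .covstats import EffectSizeMap, cohens_d_paired, coverage_map, matched_threshold
from .fitting import EXPERIMENT_GRID, GridSpec, fit_dataset
from .phantom import (HRFSpec, add_noise, build_slab, prf_timecourses,
                      simulate_prf_population, simulate_subject)
from .resampling import project_to_surface, subsample_units, upsample_volume
from .stimulus import make_bar_apertures

__all__ = ["ExperimentConfig", "run_experiment", "run_volume_vs_surface",
           "run_cnr_sweep", "run_size_sweep", "run_equal_n",
           "run_upsample_2to1", "run_cmf_fit", "derive_seed", "report_json"]

EXPERIMENT_NAMES = ("volume_vs_surface", "noiseless", "cnr_sweep", "size_sweep",
                    "equal_n", "surface_self_subsample", "upsample_2to1", "cmf_fit")


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved configuration of one phantom experiment.

    Defaults are the desk scale used throughout the test suite and the
    acceptance analyses: 10 subjects x 4 runs, a 2 mm slab of about
    19 x 20 x 3 voxels per hemifield, 135-frame bar runs rendered at
    24 x 24 px, and 64 x 64 coverage grids.
    """

    experiment: str = "volume_vs_surface"
    n_subjects: int = 10
    n_runs: int = 4
    master_seed: int = 0
    # generating cortical mapping and slab geometry
    mapping_M0: float = 14.0
    mapping_E2: float = 1.4
    max_ecc_deg: float = 7.8
    voxel_mm: float = 2.0
    depth_voxels: int = 3
    polar_span_deg: float = 180.0
    n_polar: int = 20
    sigma_slope: float = 0.1
    sigma_intercept: float = 0.5
    subject_jitter: bool = True
    anatomy_cv: float = 0.08  # between-subject lognormal scatter of M0, E2, sigma
    # stimulus / HRF
    radius_deg: float = 7.8
    bar_width_deg: float = 1.95
    n_directions: int = 8
    frames_per_sweep: int = 16
    n_blank_frames: int = 7
    stim_resolution_px: int = 24
    tr_s: float = 1.883
    # noise and fitting
    cnr: float = 2.0
    grid: str = "experiment"  # "experiment" (light) or "default" (dense)
    ve_threshold: float = 0.20
    ve_threshold_noiseless: float = 0.50
    # resampling
    vertex_spacing_mm: float = 0.95
    depth_fractions: tuple = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    interpolation: str = "trilinear"
    upsample_target_mm: float = 1.0
    # artificial populations
    n_prfs: int = 500
    center_spread_deg: float = 3.0
    pop_sigma_deg: float = 1.0
    cnr_levels: tuple = ((np.inf, np.inf), (4.0, np.inf), (2.0, np.inf))
    size_increments: tuple = (0.0, 0.25, 0.5, 1.0)
    n_subsample_draws: int = 12
    # statistics
    coverage_grid_n: int = 64
    fovea_ecc_deg: float = 1.0
    periphery_ecc_deg: float = 4.0
    n_boot: int = 50
    pairing: str = "pooled"  # or "subject_runs"

    def to_dict(self) -> dict:
        def clean(v):
            if isinstance(v, tuple):
                return [clean(x) for x in v]
            if isinstance(v, float) and np.isinf(v):
                return None
            return v

        return {k: clean(v) for k, v in asdict(self).items()}

    def content_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        kw = dict(d)
        for k in ("depth_fractions", "size_increments"):
            if k in kw:
                kw[k] = tuple(kw[k])
        if "cnr_levels" in kw:
            kw["cnr_levels"] = tuple(
                tuple(np.inf if x is None else x for x in lvl)
                for lvl in kw["cnr_levels"])
        if kw.get("cnr", 0) is None:
            kw["cnr"] = np.inf
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        from pathlib import Path

        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def derive_seed(master_seed: int, *path) -> int:
    """Deterministic child seed below 2**31, unique per (master, path)."""
    key = tuple(zlib.crc32(str(p).encode()) for p in path)
    ss = np.random.SeedSequence(int(master_seed), spawn_key=key)
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def report_json(report: dict) -> str:
    """Canonical JSON serialization of a report (for hashing/determinism)."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, EffectSizeMap):
            return None
        raise TypeError(f"not serializable: {type(o)}")

    return json.dumps(report, sort_keys=True, default=default)


# ---------------------------------------------------------------------------
# shared building blocks


def _stimulus(cfg: ExperimentConfig):
    return make_bar_apertures(
        radius_deg=cfg.radius_deg, bar_width_deg=cfg.bar_width_deg,
        n_directions=cfg.n_directions, frames_per_sweep=cfg.frames_per_sweep,
        resolution_px=cfg.stim_resolution_px, tr_s=cfg.tr_s,
        n_blank_frames=cfg.n_blank_frames)


def _grid_spec(cfg: ExperimentConfig) -> GridSpec:
    return EXPERIMENT_GRID if cfg.grid == "experiment" else GridSpec()


def _mapping(cfg: ExperimentConfig) -> CorticalMapping:
    return CorticalMapping(M0=cfg.mapping_M0, E2=cfg.mapping_E2)


def _subject_slabs(cfg: ExperimentConfig, subject: int):
    """Both hemifield slabs of one subject.

    Anatomical variability across subjects is emulated by a sub-voxel jitter
    of the slab placement and a lognormal scatter (coefficient of variation
    ``anatomy_cv``) of the subject's M0, E2 and foveal pRF size around the
    nominal values, mirroring the between-subject spread of cortical
    magnification and pRF size in real cohorts.
    """
    rng = np.random.default_rng(derive_seed(cfg.master_seed, "slab", subject))
    if cfg.subject_jitter:
        d_off = float(rng.uniform(0.0, cfg.voxel_mm))
        p_off = float(rng.uniform(-0.5, 0.5) * cfg.polar_span_deg / cfg.n_polar)
        cv = cfg.anatomy_cv
        z = rng.standard_normal(3)
        mapping = CorticalMapping(M0=cfg.mapping_M0 * float(np.exp(cv * z[0])),
                                  E2=cfg.mapping_E2 * float(np.exp(cv * z[1])))
        s_int = cfg.sigma_intercept * float(np.exp(cv * z[2]))
    else:
        d_off = p_off = 0.0
        mapping = _mapping(cfg)
        s_int = cfg.sigma_intercept
    return [
        build_slab(mapping, max_ecc_deg=cfg.max_ecc_deg, voxel_mm=cfg.voxel_mm,
                   depth_voxels=cfg.depth_voxels, polar_span_deg=cfg.polar_span_deg,
                   n_polar=cfg.n_polar, sigma_slope=cfg.sigma_slope,
                   sigma_intercept=s_int, hemifield=h,
                   d_offset_mm=d_off, polar_offset_deg=p_off)
        for h in ("right", "left")
    ]


def _coverage(cfg: ExperimentConfig, fits: pd.DataFrame, ve_threshold: float):
    return coverage_map(fits, radius_deg=cfg.radius_deg,
                        grid_n=cfg.coverage_grid_n, ve_threshold=ve_threshold)


def _group_effect(pairs_by_subject, cfg: ExperimentConfig, seed_tag: str) -> dict:
    """Pooled paired Cohen's d with a subject-level bootstrap.

    ``pairs_by_subject`` is a list (one entry per subject) of lists of
    (condition_a, condition_b) coverage-map pairs.  In ``pooled`` mode all
    pairs enter one Cohen's d map and the bootstrap resamples subjects with
    replacement, re-pooling their pairs; in ``subject_runs`` mode each
    subject gets a d map across their runs and the bootstrap averages
    subject maps.
    """
    boot_seed = derive_seed(cfg.master_seed, "boot", seed_tag)
    if cfg.pairing == "subject_runs":
        subj_maps = [cohens_d_paired([a for a, _ in p], [b for _, b in p])
                     for p in pairs_by_subject]
        boot = covstats.bootstrap_effect(subj_maps, n_boot=cfg.n_boot,
                                         seed=boot_seed)
        pooled = boot
    else:
        all_a = [a for p in pairs_by_subject for a, _ in p]
        all_b = [b for p in pairs_by_subject for _, b in p]
        pooled = cohens_d_paired(all_a, all_b)
        rng = np.random.default_rng(boot_seed)
        n_subj = len(pairs_by_subject)
        acc = np.zeros((cfg.n_boot,) + pooled.d.shape)
        for b in range(cfg.n_boot):
            idx = rng.integers(0, n_subj, size=n_subj)
            ba = [a for i in idx for a, _ in pairs_by_subject[i]]
            bb = [bm for i in idx for _, bm in pairs_by_subject[i]]
            acc[b] = cohens_d_paired(ba, bb).d
        boot = EffectSizeMap(d=acc.mean(axis=0), n_pairs=pooled.n_pairs,
                             radius_deg=pooled.radius_deg,
                             bootstrap_mean=acc.mean(axis=0),
                             bootstrap_sd=acc.std(axis=0, ddof=0),
                             n_boot=cfg.n_boot)

    summary = covstats.summarize_bias(boot, cfg.fovea_ecc_deg, cfg.periphery_ecc_deg)
    n = boot.d.shape[0]
    X, Y = np.meshgrid(np.linspace(-boot.radius_deg, boot.radius_deg, n),
                       np.linspace(-boot.radius_deg, boot.radius_deg, n),
                       indexing="xy")
    in_field = np.hypot(X, Y) <= boot.radius_deg
    return {
        "n_pairs": pooled.n_pairs,
        "n_capped_pixels": pooled.n_capped,
        "mean_d_fovea": summary["mean_d_fovea"],
        "mean_d_periphery": summary["mean_d_periphery"],
        "global_mean_d": float(boot.d[in_field].mean()),
        "max_abs_d": float(np.abs(boot.d[in_field]).max()),
        "d_map": pooled.d,
        "bootstrap_mean": boot.bootstrap_mean,
        "bootstrap_sd": boot.bootstrap_sd,
        "effect": boot,
    }


def _strip_maps(group: dict) -> dict:
    """Scalar part of a group-effect block (for compact reports)."""
    return {k: v for k, v in group.items()
            if k not in ("bootstrap_mean", "bootstrap_sd", "effect")}


def _base_report(cfg: ExperimentConfig) -> dict:
    return {"experiment": cfg.experiment, "config": cfg.to_dict(),
            "config_hash": cfg.content_hash()}


# ---------------------------------------------------------------------------
# experiments


def run_volume_vs_surface(cfg: ExperimentConfig, condition_b: str = "surface") -> dict:
    """Volume-fitted vs surface-projected-and-refitted coverage.

    Simulates each subject's slabs, fits pRFs in volume space, projects the
    time series to the emulated surface and refits there, then compares the
    two coverage conditions (surface minus volume; positive d means more
    surface coverage).  With an infinite CNR this is the noiseless variant
    (single run per subject, stricter ve threshold).  ``condition_b="volume"``
    compares the volume against itself — an identical-condition null control.
    """
    stim, hrf, grid = _stimulus(cfg), HRFSpec(tr_s=cfg.tr_s), _grid_spec(cfg)
    noiseless = np.isinf(cfg.cnr)
    n_runs = 1 if noiseless else cfg.n_runs
    ve_thr = cfg.ve_threshold_noiseless if noiseless else cfg.ve_threshold

    pairs, ve_vol_all, ve_surf_all = [], [], []
    n_vox = n_vert = 0
    for s in range(cfg.n_subjects):
        slabs = _subject_slabs(cfg, s)
        run_pairs = []
        for r in range(n_runs):
            fits_v, fits_s = [], []
            for slab in slabs:
                ds = simulate_subject(slab, stim, hrf, cnr=cfg.cnr,
                                      seed=derive_seed(cfg.master_seed, "bold",
                                                       s, r, slab.hemifield))
                fits_v.append(fit_dataset(ds, stim, hrf, grid))
                if condition_b == "surface":
                    surf = project_to_surface(ds, cfg.vertex_spacing_mm,
                                              cfg.depth_fractions, cfg.interpolation)
                    fits_s.append(fit_dataset(surf, stim, hrf, grid))
                    if s == 0 and r == 0:
                        n_vox += int(np.prod(ds.bold.shape[:2]))
                        n_vert += surf.n_units
            fv = pd.concat(fits_v, ignore_index=True)
            cov_v = _coverage(cfg, fv, ve_thr)
            if condition_b == "surface":
                fs = pd.concat(fits_s, ignore_index=True)
                cov_s = _coverage(cfg, fs, ve_thr)
                ve_vol_all.append(fv["ve"].to_numpy())
                ve_surf_all.append(fs["ve"].to_numpy())
                run_pairs.append((cov_s, cov_v))
            else:
                run_pairs.append((cov_v, cov_v))
        pairs.append(run_pairs)

    report = _base_report(cfg)
    report.update(_group_effect(pairs, cfg, "volume_vs_surface"))
    if condition_b == "surface":
        report["vertex_voxel_ratio"] = n_vert / n_vox
        ve_v = np.concatenate(ve_vol_all)
        ve_s = np.concatenate(ve_surf_all)
        t, frac_v, _ = matched_threshold(ve_v, ve_s, ve_thr)
        report["matched_surface_threshold"] = t
        report["masked_fraction_volume"] = frac_v
        report["masked_fraction_surface_at_base"] = float(np.mean(ve_s < ve_thr))
    return report


def run_cnr_sweep(cfg: ExperimentConfig) -> dict:
    """Effect of CNR differences at constant pRF size.

    For each (cnr_a, cnr_b) level, artificial-subject populations receive
    independent noise per condition and run; both sides are fitted and the
    higher-CNR condition b is compared against condition a.  The first level
    with cnr_a == cnr_b is the zero-gap null.
    """
    stim, hrf, grid = _stimulus(cfg), HRFSpec(tr_s=cfg.tr_s), _grid_spec(cfg)
    report = _base_report(cfg)
    report["levels"] = []
    for li, (cnr_a, cnr_b) in enumerate(cfg.cnr_levels):
        pairs = []
        for s in range(cfg.n_subjects):
            pop = simulate_prf_population(
                cfg.n_prfs, cfg.center_spread_deg, cfg.pop_sigma_deg,
                seed=derive_seed(cfg.master_seed, "pop", li, s))
            clean = prf_timecourses(pop, stim, hrf).T  # (n, T)
            run_pairs = []
            for r in range(cfg.n_runs):
                covs = {}
                for cond, cnr in (("a", cnr_a), ("b", cnr_b)):
                    noisy = add_noise(clean, cnr,
                                      derive_seed(cfg.master_seed, "noise",
                                                  li, s, r, cond))
                    fits = fit_dataset(noisy, stim, hrf, grid)
                    covs[cond] = _coverage(cfg, fits, cfg.ve_threshold)
                run_pairs.append((covs["b"], covs["a"]))
            pairs.append(run_pairs)
        level = {"cnr_a": None if np.isinf(cnr_a) else cnr_a,
                 "cnr_b": None if np.isinf(cnr_b) else cnr_b}
        level.update(_strip_maps(_group_effect(pairs, cfg, f"cnr_{li}")))
        report["levels"].append(level)
    report["foveal_d_curve"] = [lv["mean_d_fovea"] for lv in report["levels"]]
    return report


def run_size_sweep(cfg: ExperimentConfig) -> dict:
    """Effect of pRF size differences at equal CNR.

    Populations are compared at the coverage level (no refitting): per run,
    a population is drawn at the base size and condition b carries the same
    centers with sigma scaled by (1 + increment) — a paired manipulation of
    size alone.  The zero increment is an exact identical-data null.
    """
    report = _base_report(cfg)
    report["levels"] = []
    for li, inc in enumerate(cfg.size_increments):
        pairs = []
        for s in range(cfg.n_subjects):
            run_pairs = []
            for r in range(cfg.n_runs):
                pop_a = simulate_prf_population(
                    cfg.n_prfs, cfg.center_spread_deg, cfg.pop_sigma_deg,
                    seed=derive_seed(cfg.master_seed, "size", s, r))
                pop_b = pop_a.assign(sigma=pop_a["sigma"] * (1.0 + inc))
                run_pairs.append((_coverage(cfg, pop_b, 0.0),
                                  _coverage(cfg, pop_a, 0.0)))
            pairs.append(run_pairs)
        level = {"size_increment": inc}
        level.update(_strip_maps(_group_effect(pairs, cfg, f"size_{li}")))
        report["levels"].append(level)
    report["global_d_curve"] = [lv["global_mean_d"] for lv in report["levels"]]
    return report


def _noiseless_subject_fits(cfg: ExperimentConfig, stim, hrf, grid, s: int):
    """Noiseless volume and surface fit tables of one subject."""
    fits_v, fits_s = [], []
    for slab in _subject_slabs(cfg, s):
        ds = simulate_subject(slab, stim, hrf, cnr=np.inf)
        fits_v.append(fit_dataset(ds, stim, hrf, grid))
        surf = project_to_surface(ds, cfg.vertex_spacing_mm, cfg.depth_fractions,
                                  cfg.interpolation)
        fits_s.append(fit_dataset(surf, stim, hrf, grid))
    return pd.concat(fits_v, ignore_index=True), pd.concat(fits_s, ignore_index=True)


def run_equal_n(cfg: ExperimentConfig) -> dict:
    """Equal-N subsampling controls on the noiseless pipeline.

    (A) ``equal_n``: surface fits randomly subsampled to the volume's
    above-threshold unit count, compared against the volume — tests whether
    the surface bias is a pure unit-count effect.  (B) ``self_subsample``:
    the full surface compared against random subsamples of itself — a null
    that isolates the act of subsampling.
    """
    stim, hrf, grid = _stimulus(cfg), HRFSpec(tr_s=cfg.tr_s), _grid_spec(cfg)
    thr = cfg.ve_threshold_noiseless
    pairs_a, pairs_b = [], []
    for s in range(cfg.n_subjects):
        fits_v, fits_s = _noiseless_subject_fits(cfg, stim, hrf, grid, s)
        surf_above = fits_s[fits_s["ve"] >= thr].reset_index(drop=True)
        n_target = min(int((fits_v["ve"] >= thr).sum()), len(surf_above))
        cov_v = _coverage(cfg, fits_v, thr)
        cov_s = _coverage(cfg, fits_s, thr)
        sub = subsample_units(surf_above, n_target,
                              seed=derive_seed(cfg.master_seed, "eqn", s))
        pairs_a.append([(_coverage(cfg, sub, thr), cov_v)])
        run_pairs = []
        for r in range(cfg.n_subsample_draws):
            sub_r = subsample_units(surf_above, n_target,
                                    seed=derive_seed(cfg.master_seed, "selfsub", s, r))
            run_pairs.append((cov_s, _coverage(cfg, sub_r, thr)))
        pairs_b.append(run_pairs)

    report = _base_report(cfg)
    report["equal_n"] = _strip_maps(_group_effect(pairs_a, cfg, "equal_n"))
    report["self_subsample"] = _strip_maps(_group_effect(pairs_b, cfg, "self_sub"))
    return report


def run_upsample_2to1(cfg: ExperimentConfig) -> dict:
    """Volumetric upsampling (default 2 mm -> 1 mm, trilinear) vs original.

    The noisy 2 mm phantom is resliced to the finer grid, both resolutions
    are fitted independently, and the upsampled condition is compared
    against the original.
    """
    stim, hrf, grid = _stimulus(cfg), HRFSpec(tr_s=cfg.tr_s), _grid_spec(cfg)
    pairs = []
    for s in range(cfg.n_subjects):
        slabs = _subject_slabs(cfg, s)
        run_pairs = []
        for r in range(cfg.n_runs):
            fits_orig, fits_up = [], []
            for slab in slabs:
                ds = simulate_subject(slab, stim, hrf, cnr=cfg.cnr,
                                      seed=derive_seed(cfg.master_seed, "upsbold",
                                                       s, r, slab.hemifield))
                fits_orig.append(fit_dataset(ds, stim, hrf, grid))
                up = upsample_volume(ds, cfg.upsample_target_mm, cfg.interpolation)
                fits_up.append(fit_dataset(up, stim, hrf, grid))
            cov_o = _coverage(cfg, pd.concat(fits_orig, ignore_index=True),
                              cfg.ve_threshold)
            cov_u = _coverage(cfg, pd.concat(fits_up, ignore_index=True),
                              cfg.ve_threshold)
            run_pairs.append((cov_u, cov_o))
        pairs.append(run_pairs)
    report = _base_report(cfg)
    report.update(_group_effect(pairs, cfg, "upsample"))
    return report


def run_cmf_fit(cfg: ExperimentConfig) -> dict:
    """Recover the cortical magnification model from fitted phantom data.

    Fits pRFs on (possibly noisy) phantom volumes, attaches the exact
    cortical area each voxel represents, estimates the empirical linear CMF
    with the moving-ring method (ve >= 10%, eccentricity <= 9 deg) and fits
    M(E) = A/(E+E2), comparing the recovered parameters against the
    generating mapping.
    """
    stim, hrf, grid = _stimulus(cfg), HRFSpec(tr_s=cfg.tr_s), _grid_spec(cfg)
    tables, gen_M0, gen_E2 = [], [], []
    for s in range(cfg.n_subjects):
        slabs = _subject_slabs(cfg, s)
        gen_M0.append(slabs[0].mapping.M0)
        gen_E2.append(slabs[0].mapping.E2)
        for slab in slabs:
            ds = simulate_subject(slab, stim, hrf, cnr=cfg.cnr,
                                  seed=derive_seed(cfg.master_seed, "cmfbold",
                                                   s, slab.hemifield))
            fits = fit_dataset(ds, stim, hrf, grid)
            # per-unit cortical area, normalized so the pooled cohort covers
            # each annulus exactly once (every subject contributes a full map)
            fits["area_mm2"] = ds.truth["area_mm2"].to_numpy() / cfg.n_subjects
            tables.append(fits)
    # reference: the cohort-average mapping actually used by the generator
    mapping = CorticalMapping(M0=float(np.mean(gen_M0)), E2=float(np.mean(gen_E2)))
    pooled = pd.concat(tables, ignore_index=True)
    pooled["ecc"] = np.hypot(pooled["x"], pooled["y"])
    coverage_fraction = 2 * cfg.polar_span_deg / 360.0
    samples = estimate_cmf_moving_ring(
        pooled, ve_threshold=0.10, max_ecc_deg=9.0,
        coverage_fraction=coverage_fraction,
        max_center_ecc_deg=min(9.0, cfg.max_ecc_deg))
    fit = fit_cmf(samples)
    report = _base_report(cfg)
    report.update({
        "recovered": fit.mapping.to_dict(),
        "generating": mapping.to_dict(),
        "M0_rel_error": abs(fit.mapping.M0 - mapping.M0) / mapping.M0,
        "E2_rel_error": abs(fit.mapping.E2 - mapping.E2) / mapping.E2,
        "residual_norm": fit.residual_norm,
        "n_units_used": int(((pooled["ve"] >= 0.10) & (pooled["ecc"] <= 9.0)).sum()),
        "cmf_samples_ecc": samples.eccentricity_deg,
        "cmf_samples_mm_per_deg": samples.linear_cmf_mm_per_deg,
    })
    return report


_RUNNERS = {
    "volume_vs_surface": run_volume_vs_surface,
    "noiseless": lambda cfg: run_volume_vs_surface(replace(cfg, cnr=np.inf)),
    "cnr_sweep": run_cnr_sweep,
    "size_sweep": run_size_sweep,
    "equal_n": run_equal_n,
    "surface_self_subsample": run_equal_n,
    "upsample_2to1": lambda cfg: run_upsample_2to1(
        replace(cfg, n_runs=1, cnr=1.0, n_subjects=min(cfg.n_subjects, 8))),
    "cmf_fit": run_cmf_fit,
}


def run_experiment(name: str, cfg: ExperimentConfig) -> dict:
    """Dispatch an experiment by name with the resolved config embedded."""
    if name not in _RUNNERS:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENT_NAMES}")
    cfg = replace(cfg, experiment=name)
    return _RUNNERS[name](cfg)
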