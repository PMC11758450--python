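"""Visual-field coverage maps and paired effect-size statistics.

A coverage map represents each above-threshold pRF by a unit-height
isotropic Gaussian in visual-field space and stores, at every grid point,
the average value over pRFs — a number in [0, 1] describing how densely the
population covers that location.  Differences between processing conditions
are quantified per pixel by paired Cohen's d (mean of paired differences
over their n-1-normalized standard deviation), aggregated across subjects
by bootstrap resampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CoverageMap", "EffectSizeMap", "coverage_map", "cohens_d_paired",
           "bootstrap_effect", "matched_threshold", "summarize_bias"]

#: pixels where all paired differences vanish get d = 0; elsewhere |d| is
#: clipped to D_CAP (a vanishing difference variance would otherwise yield
#: arbitrarily large or infinite effect sizes)
D_CAP = 10.0


@dataclass
class CoverageMap:
    """Average pRF coverage on a square visual-field grid over [-R, R]^2."""

    grid: np.ndarray
    radius_deg: float
    n_prfs_used: int
    ve_threshold: float

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, float)
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("coverage grid must be square")
        if np.nanmin(g) < -1e-12 or np.nanmax(g) > 1 + 1e-12:
            raise ValueError("coverage values must lie in [0, 1]")
        if self.n_prfs_used < 1:
            raise ValueError("coverage map undefined without pRFs")
        self.grid = g


@dataclass
class EffectSizeMap:
    """Per-pixel paired Cohen's d between two coverage conditions."""

    d: np.ndarray
    n_pairs: int
    radius_deg: float
    bootstrap_mean: np.ndarray | None = None
    bootstrap_sd: np.ndarray | None = None
    n_boot: int = 0
    n_capped: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.d).all():
            raise ValueError("effect-size map must be finite everywhere")


def _grid_coords(radius_deg: float, grid_n: int):
    c = np.linspace(-radius_deg, radius_deg, grid_n)
    return np.meshgrid(c, c, indexing="xy")


def coverage_map(prfs: pd.DataFrame, radius_deg: float, grid_n: int = 128,
                 ve_threshold: float = 0.2) -> CoverageMap:
    """Average unit-height Gaussian coverage of above-threshold pRFs.

    ``prfs`` needs columns x, y, sigma, ve.  Grid nodes span [-R, R] in both
    axes inclusively (an odd ``grid_n`` places a node exactly at fixation).
    """
    sel = prfs[prfs["ve"] >= ve_threshold]
    if len(sel) == 0:
        raise ValueError("no pRFs at or above the ve threshold")
    X, Y = _grid_coords(radius_deg, grid_n)
    xs = sel["x"].to_numpy(float)
    ys = sel["y"].to_numpy(float)
    ss = sel["sigma"].to_numpy(float)
    acc = np.zeros((grid_n, grid_n))
    chunk = max(1, int(2**22 // (grid_n * grid_n)))
    for lo in range(0, len(xs), chunk):
        dx = X[None] - xs[lo:lo + chunk, None, None]
        dy = Y[None] - ys[lo:lo + chunk, None, None]
        s2 = 2.0 * ss[lo:lo + chunk, None, None] ** 2
        acc += np.exp(-(dx**2 + dy**2) / s2).sum(axis=0)
    return CoverageMap(grid=acc / len(xs), radius_deg=radius_deg,
                       n_prfs_used=len(xs), ve_threshold=ve_threshold)


def cohens_d_paired(cov_a, cov_b, cap: float = D_CAP) -> EffectSizeMap:
    """Paired Cohen's d per pixel between two equal-length lists of coverage maps.

    d = mean(a_i - b_i) / sd(a_i - b_i) with the n-1-normalized sd.  Pixels
    whose differences are all exactly zero get d = 0; everywhere else d is
    clipped to ``+/- cap`` (count reported, occurrences logged), so that
    pixels with vanishing difference variance cannot poison downstream
    averages with infinities or astronomically large values.
    """
    if len(cov_a) != len(cov_b):
        raise ValueError("paired condition lists must have equal length")
    n = len(cov_a)
    if n < 2:
        raise ValueError("paired Cohen's d needs at least 2 pairs")
    radius = cov_a[0].radius_deg
    diffs = np.stack([a.grid - b.grid for a, b in zip(cov_a, cov_b)])
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = mean / sd
    d[(sd == 0) & (mean == 0)] = 0.0
    capped = ~np.isfinite(d) | (np.abs(d) > cap)
    d[capped] = np.sign(mean[capped]) * cap
    n_capped = int(capped.sum())
    if n_capped:
        logger.info("cohens_d_paired: %d pixels capped at +/-%g", n_capped, cap)
    return EffectSizeMap(d=d, n_pairs=n, radius_deg=radius, n_capped=n_capped)


def bootstrap_effect(subject_d_maps, n_boot: int = 50, seed=None) -> EffectSizeMap:
    """Bootstrap (resample subjects with replacement) the mean Cohen's d map.

    Each iteration draws ``len(subject_d_maps)`` subjects with replacement
    and averages their d maps; the output carries the per-pixel bootstrap
    mean and sd.  Seeded and reproducible.
    """
    if len(subject_d_maps) < 2:
        raise ValueError("bootstrap needs at least 2 subject maps")
    shapes = {m.d.shape for m in subject_d_maps}
    if len(shapes) != 1:
        raise ValueError("subject d maps must share one shape")
    stack = np.stack([m.d for m in subject_d_maps])
    rng = np.random.default_rng(seed)
    n_subj = stack.shape[0]
    acc = np.zeros((n_boot,) + stack.shape[1:])
    for b in range(n_boot):
        idx = rng.integers(0, n_subj, size=n_subj)
        acc[b] = stack[idx].mean(axis=0)
    bmean = acc.mean(axis=0)
    bsd = acc.std(axis=0, ddof=0)
    return EffectSizeMap(d=bmean, n_pairs=subject_d_maps[0].n_pairs,
                         radius_deg=subject_d_maps[0].radius_deg,
                         bootstrap_mean=bmean, bootstrap_sd=bsd, n_boot=n_boot)


def matched_threshold(ve_volume, ve_surface, base_threshold: float):
    """Surface ve threshold masking the same fraction of units as the volume.

    Returns ``(t, frac_volume_masked, frac_surface_masked_at_t)`` where t is
    the empirical quantile of the surface ve distribution at the volume's
    masked fraction, i.e. fraction(ve_surface < t) matches
    fraction(ve_volume < base_threshold).
    """
    ve_v = np.asarray(ve_volume, float)
    ve_s = np.sort(np.asarray(ve_surface, float))
    if ve_v.size == 0 or ve_s.size == 0:
        raise ValueError("ve lists must be nonempty")
    if np.ptp(ve_s) == 0 or np.ptp(ve_v) == 0:
        raise ValueError("degenerate (constant) ve distribution")
    frac = float(np.mean(ve_v < base_threshold))
    k = int(round(frac * ve_s.size))
    if k <= 0:
        t = float(ve_s[0])  # mask nothing: at or below the surface minimum
    elif k >= ve_s.size:
        t = float(ve_s[-1]) + np.finfo(float).eps
    else:
        t = float(ve_s[k])
    frac_surface = float(np.mean(ve_s < t))
    return t, frac, frac_surface


def summarize_bias(eff: EffectSizeMap, fovea_ecc_deg: float = 1.0,
                   periphery_ecc_deg: float = 4.0) -> dict:
    """Mean Cohen's d inside the foveal disc and beyond the periphery ring.

    Pixels outside the inscribed circle of radius R are excluded.  Requires
    0 < fovea_ecc < periphery_ecc <= R.
    """
    R = eff.radius_deg
    if not 0 < fovea_ecc_deg < periphery_ecc_deg <= R:
        raise ValueError("need 0 < fovea_ecc < periphery_ecc <= field radius")
    n = eff.d.shape[0]
    X, Y = _grid_coords(R, n)
    ecc = np.hypot(X, Y)
    fovea = ecc < fovea_ecc_deg
    periph = (ecc > periphery_ecc_deg) & (ecc <= R)
    if not fovea.any() or not periph.any():
        raise ValueError("empty summary region at this grid resolution")
    return {"mean_d_fovea": float(eff.d[fovea].mean()),
            "mean_d_periphery": float(eff.d[periph].mean())}


def save_map_nifti(m, nifti_path, sidecar_path=None) -> None:
    """Write a coverage or effect-size map as 2-D NIfTI plus JSON metadata."""
    import json
    from pathlib import Path

    import nibabel as nib

    nifti_path = Path(nifti_path)
    grid = m.grid if isinstance(m, CoverageMap) else m.d
    px = 2 * m.radius_deg / (grid.shape[0] - 1)
    affine = np.diag([px, px, 1.0, 1.0])
    data = grid.T[:, :, np.newaxis].astype(np.float32)  # x, y, 1
    nib.save(nib.Nifti1Image(data, affine), str(nifti_path))
    if isinstance(m, CoverageMap):
        meta = {"kind": "coverage", "radius_deg": m.radius_deg,
                "n_prfs_used": m.n_prfs_used, "ve_threshold": m.ve_threshold}
    else:
        meta = {"kind": "effect_size", "radius_deg": m.radius_deg,
                "n_pairs": m.n_pairs, "n_boot": m.n_boot, "n_capped": m.n_capped}
    if sidecar_path is None:
        sidecar_path = nifti_path.with_suffix("").with_suffix(".json")
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def summaries_to_csv(summaries: dict, path) -> None:
    """Write a flat dict of named scalar summaries as a two-column CSV."""
    pd.DataFrame(sorted(summaries.items()),
                 columns=["name", "value"]).to_csv(path, index=False)


def save_quicklook(eff: EffectSizeMap, path, title: str = "") -> None:
    """Optional PNG rendering of an effect-size map (side-effect free)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    lim = eff.radius_deg
    vmax = max(1e-6, np.abs(eff.d).max())
    im = ax.imshow(eff.d, origin="lower", extent=(-lim, lim, -lim, lim),
                   cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    fig.colorbar(im, ax=ax, label="paired Cohen's d")
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
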