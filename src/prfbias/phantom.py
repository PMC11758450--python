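"""Synthetic retinotopic phantom: a flat cortical slab with known pRFs.

The phantom realizes early visual cortex as a regular 3-D voxel grid
("flat slab") rather than a folded mesh: axis 0 is cortical distance from
the occipital pole, axis 1 maps linearly to polar angle, axis 2 is cortical
depth.  Every voxel in a depth column shares one ground-truth pRF whose
eccentricity follows the exponential cortical location function of the
stored :class:`~prfbias.clf.CorticalMapping`, so the nonlinear compression
of the fovea onto cortex is exact and invertible.  BOLD time series are the
single-Gaussian pRF response to a binary aperture stimulus convolved with a
double-gamma HRF, plus seeded Gaussian noise at a controlled
contrast-to-noise ratio (CNR = std(signal)/std(noise)).

Two hemifields are simulated as mirror slabs (default 180 deg of polar
angle each, tiled cell-centered so the pooled pair covers the full field
exactly once) and combined downstream for full-field coverage maps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .clf import CorticalMapping, clf_distance, clf_eccentricity, cortical_patch_area
from .stimulus import StimulusSequence

__all__ = [
    "PRFParams", "HRFSpec", "Slab", "PhantomDataset", "SurfaceDataset",
    "build_slab", "prf_timecourse", "add_noise", "simulate_subject",
    "simulate_prf_population",
]


@dataclass(frozen=True)
class PRFParams:
    """A single population receptive field: center (deg), size (deg), fit quality."""

    x_deg: float
    y_deg: float
    sigma_deg: float
    ve: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_deg <= 0:
            raise ValueError("sigma_deg must be positive")
        if not 0 <= self.ve <= 1:
            raise ValueError("ve must lie in [0, 1]")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x_deg, self.y_deg))


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma hemodynamic response function.

    Defaults are the widely used canonical shape: response peak at 6 s,
    undershoot peak at 16 s, unit dispersions, undershoot ratio 1/6.
    """

    tr_s: float = 1.883
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0

    def __post_init__(self) -> None:
        if self.duration_s < 20.0:
            raise ValueError("HRF kernel must cover at least 20 s")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")

    def kernel(self) -> np.ndarray:
        """Sampled causal kernel at the TR, normalized to unit peak."""
        t = np.arange(0.0, self.duration_s + 1e-9, self.tr_s)
        h = gamma_dist.pdf(t, self.peak_delay_s / self.peak_dispersion_s,
                           scale=self.peak_dispersion_s)
        h = h - self.undershoot_ratio * gamma_dist.pdf(
            t, self.undershoot_delay_s / self.undershoot_dispersion_s,
            scale=self.undershoot_dispersion_s)
        peak = np.abs(h).max()
        if not np.isfinite(peak) or peak == 0:
            raise ValueError("degenerate HRF kernel")
        return h / peak


@dataclass(frozen=True)
class Slab:
    """Ground-truth voxel grid of one hemifield (no BOLD data yet).

    ``truth`` has one row per depth column (axes 0 x 1) with the shared pRF
    parameters and the exact cortical area (mm^2) each column represents.
    """

    truth: pd.DataFrame  # columns: i, j, d_mm, theta_deg, ecc, x, y, sigma, area_mm2
    shape: tuple  # (n_distance, n_polar, n_depth)
    voxel_mm: float
    mapping: CorticalMapping
    polar_span_deg: float
    hemifield: str

    @property
    def n_columns(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def voxel_truth(self) -> pd.DataFrame:
        """Per-voxel truth table (columns replicated across depth, area split)."""
        n_depth = self.shape[2]
        rows = self.truth.loc[self.truth.index.repeat(n_depth)].reset_index(drop=True)
        rows["k"] = np.tile(np.arange(n_depth), len(self.truth))
        rows["area_mm2"] = rows["area_mm2"] / n_depth
        return rows


def build_slab(
    mapping: CorticalMapping,
    max_ecc_deg: float = 7.8,
    voxel_mm: float = 2.0,
    depth_voxels: int = 3,
    polar_span_deg: float = 180.0,
    n_polar: int = 20,
    sigma_slope: float = 0.1,
    sigma_intercept: float = 0.5,
    hemifield: str = "right",
    d_offset_mm: float = 0.0,
    polar_offset_deg: float = 0.0,
) -> Slab:
    """Construct the ground-truth voxel grid of one hemifield.

    Distance-axis voxels sit at d = d_offset + i * voxel_mm for
    i = 0 .. ceil(d_max/voxel_mm) - 1 with d_max = clf_distance(max_ecc);
    polar-axis voxels tile ``polar_span_deg`` centered on the horizontal
    meridian (0 deg for the right hemifield, 180 for the left).  Truth pRF
    size follows sigma = sigma_intercept + sigma_slope * eccentricity.
    ``d_offset_mm``/``polar_offset_deg`` jitter the grid placement to emulate
    anatomical variability across subjects.
    """
    d_max = clf_distance(max_ecc_deg, mapping)
    n_d = int(np.ceil(d_max / voxel_mm))
    if n_d < 3 or n_polar < 3 or depth_voxels < 1:
        raise ValueError("slab must be at least 3 voxels long on in-sheet axes")
    if hemifield not in ("right", "left"):
        raise ValueError("hemifield must be 'right' or 'left'")

    center = 0.0 if hemifield == "right" else 180.0
    dtheta = polar_span_deg / n_polar
    i_idx, j_idx = np.meshgrid(np.arange(n_d), np.arange(n_polar), indexing="ij")
    i_idx, j_idx = i_idx.ravel(), j_idx.ravel()
    d = d_offset_mm + i_idx * voxel_mm
    theta = center + polar_offset_deg + dtheta * (j_idx + 0.5) - polar_span_deg / 2
    ecc = clf_eccentricity(d, mapping)
    sigma = sigma_intercept + sigma_slope * ecc
    th_rad = np.deg2rad(theta)

    # exact cortical area per column: annular sector between the half-step
    # eccentricity bounds of the column, under the isotropic magnification model
    e_lo = clf_eccentricity(np.maximum(d - voxel_mm / 2, 0.0), mapping)
    e_hi = clf_eccentricity(d + voxel_mm / 2, mapping)
    area = np.array([
        cortical_patch_area(lo, hi, np.deg2rad(dtheta), mapping)
        for lo, hi in zip(e_lo, e_hi)
    ])

    truth = pd.DataFrame({
        "i": i_idx, "j": j_idx, "d_mm": d, "theta_deg": theta, "ecc": ecc,
        "x": ecc * np.cos(th_rad), "y": ecc * np.sin(th_rad),
        "sigma": sigma, "area_mm2": area,
    })
    return Slab(truth=truth, shape=(n_d, n_polar, depth_voxels), voxel_mm=voxel_mm,
                mapping=mapping, polar_span_deg=polar_span_deg, hemifield=hemifield)


# ---------------------------------------------------------------------------
# forward model


def _gaussian_images(x, y, sigma, stim: StimulusSequence) -> np.ndarray:
    """Unit-height isotropic Gaussians over the stimulus pixel grid, (n, P)."""
    X, Y = stim.pixel_centers()
    Xf, Yf = X.ravel()[None, :], Y.ravel()[None, :]
    x = np.atleast_1d(np.asarray(x, float))[:, None]
    y = np.atleast_1d(np.asarray(y, float))[:, None]
    s = np.atleast_1d(np.asarray(sigma, float))[:, None]
    return np.exp(-((Xf - x) ** 2 + (Yf - y) ** 2) / (2.0 * s**2))


def convolve_hrf(neural: np.ndarray, hrf: HRFSpec) -> np.ndarray:
    """Causal convolution with the HRF kernel, truncated to the input length.

    ``neural`` is (T,) or (T, n); convolution acts along the time axis.
    """
    kern = hrf.kernel()
    T = neural.shape[0]
    n_fft = int(2 ** np.ceil(np.log2(T + len(kern))))
    F = np.fft.rfft(neural, n=n_fft, axis=0)
    K = np.fft.rfft(kern, n=n_fft)
    out = np.fft.irfft(F * (K[:, None] if neural.ndim == 2 else K), n=n_fft, axis=0)
    return out[:T]


def prf_timecourses(params: pd.DataFrame, stim: StimulusSequence, hrf: HRFSpec,
                    amplitude: float = 1.0) -> np.ndarray:
    """Noiseless BOLD for many pRFs at once; returns (T, n)."""
    if abs(stim.tr_s - hrf.tr_s) > 1e-9:
        raise ValueError("stimulus and HRF must share the same TR")
    sig = np.asarray(params["sigma"], float)
    if np.any(sig < stim.deg_per_pixel / 2):
        warnings.warn("pRF sigma below half a stimulus pixel: responses may alias",
                      RuntimeWarning, stacklevel=2)
    G = _gaussian_images(params["x"], params["y"], sig, stim)  # (n, P)
    S = stim.frames.reshape(stim.n_frames, -1).astype(float)  # (T, P)
    neural = S @ G.T  # (T, n)
    return amplitude * convolve_hrf(neural, hrf)


def prf_timecourse(prf: PRFParams, stim: StimulusSequence, hrf: HRFSpec,
                   amplitude: float = 1.0) -> np.ndarray:
    """Noiseless BOLD time series of a single pRF (deterministic)."""
    df = pd.DataFrame({"x": [prf.x_deg], "y": [prf.y_deg], "sigma": [prf.sigma_deg]})
    return prf_timecourses(df, stim, hrf, amplitude)[:, 0]


def add_noise(ts: np.ndarray, cnr: float, seed, ar1_rho: float = 0.0) -> np.ndarray:
    """Add i.i.d. (optionally AR(1)) Gaussian noise at a fixed CNR.

    Noise std is std(ts)/cnr per series (time on the last axis for 2-D
    input).  ``cnr=np.inf`` returns an unchanged copy.
    """
    ts = np.asarray(ts, float)
    if np.isinf(cnr):
        return ts.copy()
    if cnr <= 0:
        raise ValueError("cnr must be positive or infinite")
    sd = ts.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("CNR is undefined for a constant time series")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(ts.shape)
    if ar1_rho:
        if not -1 < ar1_rho < 1:
            raise ValueError("ar1_rho must lie in (-1, 1)")
        for t in range(1, ts.shape[-1]):
            noise[..., t] = ar1_rho * noise[..., t - 1] + \
                np.sqrt(1 - ar1_rho**2) * noise[..., t]
    return ts + (sd / cnr) * noise


# ---------------------------------------------------------------------------
# datasets


@dataclass
class PhantomDataset:
    """Voxel-grid BOLD time series with (optional) ground truth.

    ``bold`` is (nx, ny, nz, T) on the slab axes (distance, polar, depth).
    ``truth`` is the per-voxel table (None after resampling operations that
    invalidate it).  ``geometry`` records axis roles and the generating
    cortical mapping.
    """

    bold: np.ndarray
    voxel_mm: float
    truth: pd.DataFrame | None
    geometry: dict
    cnr: float
    seed: int | None = None
    flags: np.ndarray | None = None  # per-voxel validity (resampling bookkeeping)

    @property
    def n_units(self) -> int:
        return int(np.prod(self.bold.shape[:3]))

    @property
    def n_frames(self) -> int:
        return self.bold.shape[3]

    def unit_timeseries(self) -> np.ndarray:
        """(n_units, T) view in C order of the voxel grid."""
        return self.bold.reshape(-1, self.n_frames)


@dataclass
class SurfaceDataset:
    """Vertex time series produced by emulated volume-to-surface projection."""

    vertices_mm: np.ndarray  # (n_vertices, 2) in-sheet (distance, polar) mm
    bold: np.ndarray  # (n_vertices, T)
    truth: pd.DataFrame | None
    depth_fractions: tuple
    source_voxel_mm: float
    vertex_spacing_mm: float
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_sheet = self.geometry.get("source_in_sheet_voxels")
        if n_sheet:
            expected = (self.source_voxel_mm / self.vertex_spacing_mm) ** 2
            ratio = len(self.bold) / n_sheet
            if abs(ratio - expected) / expected > 0.10:
                # lattice edge effects can push very small slabs outside the
                # nominal density band; surface semantics still hold
                warnings.warn(
                    f"vertex/voxel density ratio {ratio:.2f} deviates >10% from "
                    f"({self.source_voxel_mm}/{self.vertex_spacing_mm})^2 = "
                    f"{expected:.2f}", RuntimeWarning, stacklevel=2)

    @property
    def n_units(self) -> int:
        return self.bold.shape[0]

    @property
    def n_frames(self) -> int:
        return self.bold.shape[1]

    def unit_timeseries(self) -> np.ndarray:
        return self.bold


def simulate_subject(slab: Slab, stim: StimulusSequence, hrf: HRFSpec,
                     cnr: float = 2.0, seed=None, amplitude: float = 1.0,
                     noise_reference: str = "mean_signal") -> PhantomDataset:
    """Simulate one run of BOLD data for every voxel of a slab.

    Each depth column's noiseless response is computed once and replicated
    across depth; independent Gaussian noise is then drawn per voxel.  With
    the default ``noise_reference="mean_signal"`` a single noise floor is
    used for the whole slab (sd = mean signal sd across columns divided by
    ``cnr``), the way scanner thermal noise is flat across voxels while
    response amplitude varies — voxels with weak responses (small pRFs)
    then genuinely have lower CNR.  ``noise_reference="per_voxel"`` instead
    fixes every voxel's individual CNR.  Identical seeds give identical
    datasets.
    """
    col_ts = prf_timecourses(slab.truth, stim, hrf, amplitude)  # (T, n_cols)
    n_d, n_p, n_z = slab.shape
    T = col_ts.shape[0]
    bold = np.repeat(
        col_ts.T.reshape(n_d, n_p, 1, T), n_z, axis=2
    )
    if not np.isinf(cnr):
        flat = bold.reshape(-1, T)
        if noise_reference == "mean_signal":
            sd = float(col_ts.std(axis=0).mean())
            if sd == 0:
                raise ValueError("CNR undefined: slab has no stimulus response")
            rng = np.random.default_rng(seed)
            flat = flat + (sd / cnr) * rng.standard_normal(flat.shape)
        elif noise_reference == "per_voxel":
            flat = add_noise(flat, cnr, seed)
        else:
            raise ValueError("noise_reference must be 'mean_signal' or 'per_voxel'")
        bold = flat.reshape(n_d, n_p, n_z, T)
    geometry = {
        "axes": ("distance", "polar", "depth"),
        "mapping": slab.mapping.to_dict(),
        "polar_span_deg": slab.polar_span_deg,
        "hemifield": slab.hemifield,
        "shape": list(slab.shape),
    }
    return PhantomDataset(bold=bold, voxel_mm=slab.voxel_mm,
                          truth=slab.voxel_truth(), geometry=geometry,
                          cnr=cnr, seed=seed)


def simulate_prf_population(n_prfs: int, center_spread_deg: float = 3.0,
                            sigma_deg: float = 1.0, seed=None) -> pd.DataFrame:
    """Draw an artificial-subject pRF population.

    Centers follow an isotropic 2-D Gaussian about fixation (the foveal
    concentration of measured pRF samples); size is constant and ve is 1 so
    the table can feed coverage analyses directly, bypassing fitting.
    """
    if n_prfs < 1:
        raise ValueError("n_prfs must be at least 1")
    if center_spread_deg <= 0:
        raise ValueError("center_spread_deg must be positive")
    rng = np.random.default_rng(seed)
    xy = rng.normal(0.0, center_spread_deg, size=(n_prfs, 2))
    return pd.DataFrame({
        "x": xy[:, 0], "y": xy[:, 1],
        "sigma": np.full(n_prfs, float(sigma_deg)),
        "ve": np.ones(n_prfs),
    })


# ---------------------------------------------------------------------------
# I/O


def save_phantom(ds: PhantomDataset, nifti_path, sidecar_path=None) -> None:
    """Write a phantom as 4-D NIfTI plus a JSON sidecar with truth and geometry."""
    from pathlib import Path

    nifti_path = Path(nifti_path)
    affine = np.diag([ds.voxel_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(ds.bold.astype(np.float32), affine), str(nifti_path))
    meta = {
        "voxel_mm": ds.voxel_mm, "cnr": None if np.isinf(ds.cnr) else ds.cnr,
        "seed": ds.seed, "geometry": ds.geometry,
        "truth": None if ds.truth is None else ds.truth.to_dict(orient="list"),
    }
    if sidecar_path is None:
        sidecar_path = nifti_path.with_suffix("").with_suffix(".json")
    Path(sidecar_path).write_text(json.dumps(meta))


def load_phantom(nifti_path, sidecar_path=None) -> PhantomDataset:
    from pathlib import Path

    nifti_path = Path(nifti_path)
    if sidecar_path is None:
        sidecar_path = nifti_path.with_suffix("").with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    bold = np.asanyarray(nib.load(str(nifti_path)).dataobj).astype(float)
    truth = None if meta["truth"] is None else pd.DataFrame(meta["truth"])
    cnr = np.inf if meta["cnr"] is None else meta["cnr"]
    return PhantomDataset(bold=bold, voxel_mm=meta["voxel_mm"], truth=truth,
                          geometry=meta["geometry"], cnr=cnr, seed=meta["seed"])
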