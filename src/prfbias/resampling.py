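"""Spatial resampling operations whose effect on pRF results is under study.

Implements the transforms applied to phantom data: volumetric upsampling
(reslicing to a finer isotropic grid), emulated volume-to-surface projection
(a vertex lattice denser than the voxel grid, sampled at several cortical
depths and averaged, as FreeSurfer's mri_vol2surf does), random equal-N
subsampling, substitution of measured time series by their noiseless model
fits, and direct interpolation of fitted parameter maps to the surface.

Grid convention for reslicing: source and target share the center of the
first voxel, and target samples never extend beyond the source extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .phantom import HRFSpec, PhantomDataset, SurfaceDataset, prf_timecourses
from .stimulus import StimulusSequence

logger = logging.getLogger(__name__)

__all__ = ["ResampleSpec", "upsample_volume", "project_to_surface",
           "subsample_units", "substitute_noiseless", "project_parameters"]

_ORDER = {"trilinear": 1, "nearest": 0}

DEFAULT_DEPTH_FRACTIONS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class ResampleSpec:
    """Serializable description of a resampling operation."""

    kind: str  # vol2vol | vol2surf | subsample | noiseless_substitute | param_project
    interpolation: str = "trilinear"
    target_voxel_mm: float | None = None
    vertex_spacing_mm: float | None = None
    depth_fractions: tuple = DEFAULT_DEPTH_FRACTIONS
    seed: int | None = None

    def __post_init__(self) -> None:
        kinds = {"vol2vol", "vol2surf", "subsample", "noiseless_substitute",
                 "param_project"}
        if self.kind not in kinds:
            raise ValueError(f"unknown resample kind {self.kind!r}")
        if self.interpolation not in _ORDER:
            raise ValueError(f"interpolation must be one of {sorted(_ORDER)}")
        df = tuple(self.depth_fractions)
        if list(df) != sorted(df) or any(not 0 <= f <= 1 for f in df):
            raise ValueError("depth_fractions must be sorted and within [0, 1]")
        object.__setattr__(self, "depth_fractions", df)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "interpolation": self.interpolation,
                "target_voxel_mm": self.target_voxel_mm,
                "vertex_spacing_mm": self.vertex_spacing_mm,
                "depth_fractions": list(self.depth_fractions), "seed": self.seed}


def _resample_frames(vol4d: np.ndarray, coords: np.ndarray, order: int) -> np.ndarray:
    """Sample a (nx, ny, nz, T) volume at voxel-space points (3, n) per frame."""
    T = vol4d.shape[3]
    out = np.empty((coords.shape[1], T))
    for t in range(T):
        out[:, t] = map_coordinates(vol4d[..., t], coords, order=order,
                                    mode="nearest")
    return out


def upsample_volume(dataset: PhantomDataset, target_mm: float,
                    interpolation: str = "trilinear") -> PhantomDataset:
    """Reslice every time frame onto a finer isotropic grid.

    The ground-truth table is not carried over: after interpolation the
    voxel-to-truth correspondence no longer holds, and downstream analyses
    refit the resampled time series.
    """
    if target_mm >= dataset.voxel_mm:
        raise ValueError("target resolution must be finer than the source")
    ratio = dataset.voxel_mm / target_mm
    if interpolation == "nearest" and abs(ratio - round(ratio)) > 1e-9:
        logger.warning("nearest-neighbor reslice with non-integer ratio %.3f", ratio)
    order = _ORDER[interpolation]

    nx, ny, nz, T = dataset.bold.shape
    step = target_mm / dataset.voxel_mm  # target spacing in source voxel units
    axes = [np.arange(0.0, n - 1 + 1e-9, step) for n in (nx, ny, nz)]
    grid = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    new_shape = tuple(len(a) for a in axes)
    flat = _resample_frames(dataset.bold, coords, order)
    geometry = dict(dataset.geometry)
    geometry["resampled_from_mm"] = dataset.voxel_mm
    geometry["shape"] = list(new_shape)
    return PhantomDataset(bold=flat.reshape(*new_shape, T), voxel_mm=target_mm,
                          truth=None, geometry=geometry, cnr=dataset.cnr,
                          seed=dataset.seed)


def _vertex_lattice(dataset: PhantomDataset, vertex_spacing_mm: float):
    """Regular vertex lattice over the in-sheet plane, in mm and voxel units."""
    nx, ny = dataset.bold.shape[:2]
    v = dataset.voxel_mm
    ax = np.arange(0.0, (nx - 1) * v + 1e-9, vertex_spacing_mm)
    ay = np.arange(0.0, (ny - 1) * v + 1e-9, vertex_spacing_mm)
    GX, GY = np.meshgrid(ax, ay, indexing="ij")
    verts_mm = np.column_stack([GX.ravel(), GY.ravel()])
    return verts_mm, verts_mm / v


def project_to_surface(
    dataset: PhantomDataset,
    vertex_spacing_mm: float = 0.95,
    depth_fractions=DEFAULT_DEPTH_FRACTIONS,
    interpolation: str = "trilinear",
) -> SurfaceDataset:
    """Emulate volume-to-surface projection with cortical depth averaging.

    Vertices form a regular lattice (default spacing 0.95 mm, chosen so the
    areal vertex/voxel density ratio is (2/0.95)^2, about 4.4) in the
    distance x polar plane.  Each vertex samples the volume at every depth
    fraction of the cortical thickness with the chosen kernel and averages
    the sampled series across depth.
    """
    if dataset.bold.shape[2] < 2:
        raise ValueError("dataset needs at least 2 depth voxels to project")
    order = _ORDER[interpolation]
    fracs = tuple(depth_fractions)
    nz = dataset.bold.shape[2]
    verts_mm, verts_vox = _vertex_lattice(dataset, vertex_spacing_mm)
    n_vert = len(verts_mm)

    depth_coords = np.array(fracs) * (nz - 1)
    coords = np.empty((3, n_vert * len(fracs)))
    for f_i, zc in enumerate(depth_coords):
        sl = slice(f_i * n_vert, (f_i + 1) * n_vert)
        coords[0, sl] = verts_vox[:, 0]
        coords[1, sl] = verts_vox[:, 1]
        coords[2, sl] = zc
    sampled = _resample_frames(dataset.bold, coords, order)
    bold = sampled.reshape(len(fracs), n_vert, -1).mean(axis=0)

    truth = None
    if dataset.truth is not None:
        truth = _interp_params_to_vertices(dataset, verts_vox, fracs, order)

    geometry = dict(dataset.geometry)
    geometry["source_in_sheet_voxels"] = int(np.prod(dataset.bold.shape[:2]))
    return SurfaceDataset(vertices_mm=verts_mm, bold=bold, truth=truth,
                          depth_fractions=fracs, source_voxel_mm=dataset.voxel_mm,
                          vertex_spacing_mm=vertex_spacing_mm, geometry=geometry)


def _interp_params_to_vertices(dataset: PhantomDataset, verts_vox, fracs, order,
                               columns=("x", "y", "sigma", "ve"),
                               table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Interpolate per-voxel parameter maps to vertex positions (depth-averaged)."""
    shape = dataset.bold.shape[:3]
    nz = shape[2]
    df = dataset.truth if table is None else table
    out = {}
    depth_coords = np.array(fracs) * (nz - 1)
    n_vert = len(verts_vox)
    coords = np.empty((3, n_vert * len(fracs)))
    for f_i, zc in enumerate(depth_coords):
        sl = slice(f_i * n_vert, (f_i + 1) * n_vert)
        coords[0, sl] = verts_vox[:, 0]
        coords[1, sl] = verts_vox[:, 1]
        coords[2, sl] = zc
    for col in columns:
        if col not in df.columns:
            continue
        vol = np.asarray(df[col], float).reshape(shape)
        samp = map_coordinates(vol, coords, order=order, mode="nearest")
        out[col] = samp.reshape(len(fracs), n_vert).mean(axis=0)
    return pd.DataFrame(out)


def project_parameters(
    dataset: PhantomDataset,
    fits: pd.DataFrame,
    vertex_spacing_mm: float = 0.95,
    depth_fractions=DEFAULT_DEPTH_FRACTIONS,
    interpolation: str = "trilinear",
) -> pd.DataFrame:
    """Project fitted pRF parameters (not time series) to the vertex lattice.

    Each parameter field (x, y, sigma, ve) is interpolated independently to
    the vertex positions with the same depth-sampling and averaging scheme
    as :func:`project_to_surface` applied to parameter maps.
    """
    if len(fits) != np.prod(dataset.bold.shape[:3]):
        raise ValueError("need one fit per voxel of the dataset")
    _, verts_vox = _vertex_lattice(dataset, vertex_spacing_mm)
    out = _interp_params_to_vertices(dataset, verts_vox, tuple(depth_fractions),
                                     _ORDER[interpolation], table=fits)
    out.insert(0, "id", np.arange(len(out)))
    return out


def subsample_units(obj, n_target: int, seed):
    """Uniform random subset (without replacement) of units; seeded.

    Accepts a fit table (DataFrame) or a :class:`SurfaceDataset`; returns
    the same type.
    """
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    if isinstance(obj, pd.DataFrame):
        n = len(obj)
    elif isinstance(obj, SurfaceDataset):
        n = obj.n_units
    else:
        raise TypeError("subsample_units expects a DataFrame or SurfaceDataset")
    if n_target > n:
        raise ValueError(f"n_target={n_target} exceeds available units ({n})")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=n_target, replace=False))
    if isinstance(obj, pd.DataFrame):
        return obj.iloc[idx].reset_index(drop=True)
    geometry = dict(obj.geometry)
    geometry.pop("source_in_sheet_voxels", None)  # density invariant no longer applies
    return SurfaceDataset(
        vertices_mm=obj.vertices_mm[idx], bold=obj.bold[idx],
        truth=None if obj.truth is None else obj.truth.iloc[idx].reset_index(drop=True),
        depth_fractions=obj.depth_fractions, source_voxel_mm=obj.source_voxel_mm,
        vertex_spacing_mm=obj.vertex_spacing_mm, geometry=geometry)


def substitute_noiseless(dataset: PhantomDataset, fits: pd.DataFrame,
                         stim: StimulusSequence, hrf: HRFSpec) -> PhantomDataset:
    """Replace each voxel's series by the noise-free model of its fit.

    Voxels with failed fits (``ok`` False or non-finite parameters) are
    zeroed and flagged; the returned dataset is noiseless (CNR infinite) and
    idempotent under repeated substitution.
    """
    shape = dataset.bold.shape
    if len(fits) != np.prod(shape[:3]):
        raise ValueError("need one fit per voxel of the dataset")
    good = np.asarray(fits.get("ok", np.ones(len(fits), bool)), bool)
    good &= np.isfinite(fits[["x", "y", "sigma"]].to_numpy(float)).all(axis=1)
    good &= fits["sigma"].to_numpy(float) > 0

    bold = np.zeros((len(fits), shape[3]))
    sub = fits.loc[good]
    model = prf_timecourses(sub, stim, hrf)  # (T, n_good)
    amp = sub["amplitude"].to_numpy(float) if "amplitude" in sub else 1.0
    bold[good] = (model * amp).T
    geometry = dict(dataset.geometry)
    geometry["noiseless_substituted"] = True
    return PhantomDataset(bold=bold.reshape(shape), voxel_mm=dataset.voxel_mm,
                          truth=dataset.truth, geometry=geometry, cnr=np.inf,
                          seed=dataset.seed, flags=good.reshape(shape[:3]))
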