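"""Cortical location function (CLF) and cortical magnification (CMF) models.

The mapping between cortical distance from the occipital pole, ``d`` (mm),
and visual-field eccentricity, ``E`` (deg), is modeled as an exponential
cortical location function

    E(d) = E2 * (exp(d / (M0 * E2)) - 1)

with foveal magnification ``M0`` (mm/deg) and ``E2`` (deg), the eccentricity
at which the inverse magnification doubles its foveal value.  The associated
linear cortical magnification function is the hyperbolic form

    M(E) = A / (E + E2),    A = M0 * E2  (mm)

so that d(E) = integral of M from 0 to E.  This module houses the forward and
inverse mappings, the empirical moving-ring CMF estimator, and least-squares
fitting of the hyperbolic model to empirical linear-CMF samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CorticalMapping",
    "EmpiricalCMFSamples",
    "clf_eccentricity",
    "clf_distance",
    "cmf_linear",
    "estimate_cmf_moving_ring",
    "fit_cmf",
    "read_prf_table",
    "write_prf_table",
]


@dataclass(frozen=True)
class CorticalMapping:
    """Parameters of the exponential cortical location function.

    Attributes
    ----------
    M0 : float
        Cortical magnification factor at the fovea, mm/deg.
    E2 : float
        Eccentricity (deg) at which inverse magnification doubles.
    """

    M0: float
    E2: float

    def __post_init__(self) -> None:
        if not (self.M0 > 0 and self.E2 > 0):
            raise ValueError(f"M0 and E2 must be positive, got {self.M0}, {self.E2}")

    @property
    def A(self) -> float:
        """Cortical scaling factor A = M0 * E2, in mm."""
        return self.M0 * self.E2

    def to_dict(self) -> dict:
        return {"M0": self.M0, "E2": self.E2, "A": self.A}


def clf_eccentricity(d_mm, mapping: CorticalMapping):
    """Map cortical distance (mm from the occipital pole) to eccentricity (deg).

    E(d) = E2 * (exp(d / (M0*E2)) - 1); strictly increasing, E(0) = 0.
    """
    d = np.asarray(d_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("cortical distance must be nonnegative")
    out = mapping.E2 * np.expm1(d / mapping.A)
    return float(out) if np.isscalar(d_mm) else out


def clf_distance(eccentricity_deg, mapping: CorticalMapping):
    """Analytic inverse of :func:`clf_eccentricity`: d = A * ln(E/E2 + 1)."""
    e = np.asarray(eccentricity_deg, dtype=float)
    if np.any(e < 0):
        raise ValueError("eccentricity must be nonnegative")
    out = mapping.A * np.log1p(e / mapping.E2)
    return float(out) if np.isscalar(eccentricity_deg) else out


def cmf_linear(eccentricity_deg, mapping: CorticalMapping):
    """Linear cortical magnification M(E) = A / (E + E2), mm/deg."""
    e = np.asarray(eccentricity_deg, dtype=float)
    if np.any(e < 0):
        raise ValueError("eccentricity must be nonnegative")
    out = mapping.A / (e + mapping.E2)
    return float(out) if np.isscalar(eccentricity_deg) else out


def cortical_patch_area(e_lo: float, e_hi: float, dtheta_rad: float,
                        mapping: CorticalMapping) -> float:
    """Exact cortical surface area (mm^2) of a visual-field patch.

    Under an isotropic magnification model the cortical area of the annular
    sector [e_lo, e_hi] x dtheta is  dtheta * int_{e_lo}^{e_hi} M(E)^2 E dE,
    which has the closed form used here.
    """
    if e_hi < e_lo or e_lo < 0:
        raise ValueError("invalid eccentricity bounds")
    A, E2 = mapping.A, mapping.E2

    def F(e):
        return A * A * (np.log(e + E2) + E2 / (e + E2))

    return dtheta_rad * (F(e_hi) - F(e_lo))


@dataclass
class EmpiricalCMFSamples:
    """Moving-ring samples of the linear cortical magnification function."""

    eccentricity_deg: np.ndarray
    linear_cmf_mm_per_deg: np.ndarray
    ring_width_deg: float
    n_units_per_ring: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.eccentricity_deg, float)
        m = np.asarray(self.linear_cmf_mm_per_deg, float)
        if e.ndim != 1 or e.shape != m.shape:
            raise ValueError("eccentricity and CMF samples must be 1-D and aligned")
        if np.any(np.diff(e) <= 0):
            raise ValueError("eccentricities must be strictly increasing")
        if np.any(e <= 0):
            raise ValueError("eccentricities must be positive")
        if np.any(m < 0):
            raise ValueError("linear CMF values must be nonnegative")
        self.eccentricity_deg = e
        self.linear_cmf_mm_per_deg = m
        self.n_units_per_ring = np.asarray(self.n_units_per_ring, int)

    def to_json(self) -> str:
        return json.dumps({
            "eccentricity_deg": self.eccentricity_deg.tolist(),
            "linear_cmf_mm_per_deg": self.linear_cmf_mm_per_deg.tolist(),
            "ring_width_deg": self.ring_width_deg,
            "n_units_per_ring": self.n_units_per_ring.tolist(),
        })


def estimate_cmf_moving_ring(
    prf_table: pd.DataFrame,
    ve_threshold: float = 0.10,
    max_ecc_deg: float = 9.0,
    ring_width_deg: float = 1.0,
    step_deg: float = 0.25,
    coverage_fraction: float = 1.0,
    max_center_ecc_deg: float | None = None,
) -> EmpiricalCMFSamples:
    """Estimate the empirical linear CMF with a moving-ring (annulus) window.

    For each window center ``e`` the areal CMF is the summed cortical area of
    units with eccentricity inside [e - w/2, e + w/2], divided by the visual
    area of that annulus; the linear CMF is its square root.  Units are
    filtered to ``ve >= ve_threshold`` and ``eccentricity <= max_ecc_deg``.

    Parameters
    ----------
    prf_table : DataFrame
        Must carry columns ``ecc`` (deg), ``ve`` and ``area_mm2`` (cortical
        surface area represented by each unit).  A table with ``x``/``y``
        columns but no ``ecc`` gets eccentricity computed.
    coverage_fraction : float
        Fraction of each full annulus actually represented by the data
        (e.g. a phantom covering 320 of 360 deg of polar angle passes 320/360);
        the annulus area is scaled down accordingly.
    max_center_ecc_deg : float, optional
        Upper bound on ring centers, so that no window extends beyond the
        eccentricity range the data actually cover (windows hanging over the
        edge of the mapped field would underestimate the areal CMF).
        Defaults to ``max_ecc_deg``.
    """
    df = prf_table.copy()
    if "ecc" not in df.columns:
        df["ecc"] = np.hypot(df["x"], df["y"])
    for col in ("ve", "area_mm2"):
        if col not in df.columns:
            raise ValueError(f"prf_table lacks required column {col!r}")
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    df = df[(df["ve"] >= ve_threshold) & (df["ecc"] <= max_ecc_deg)]
    if len(df) == 0:
        raise ValueError("no units survive the ve/eccentricity filter")

    w = ring_width_deg
    center_cap = max_ecc_deg if max_center_ecc_deg is None else max_center_ecc_deg
    centers = np.arange(w / 2, center_cap - w / 2 + 1e-9, step_deg)
    ecc = df["ecc"].to_numpy()
    area = df["area_mm2"].to_numpy()

    keep_e, keep_m, keep_n = [], [], []
    for e in centers:
        lo, hi = e - w / 2, e + w / 2
        sel = (ecc >= lo) & (ecc < hi)
        n = int(sel.sum())
        if n == 0:
            keep_n.append(0)  # recorded, sample omitted
            continue
        annulus = np.pi * (hi**2 - lo**2) * coverage_fraction
        areal = area[sel].sum() / annulus  # mm^2 / deg^2
        # assign the sample to the area-weighted mean eccentricity in the ring;
        # this reduces the window-averaging bias of the hyperbolic profile
        e_samp = float(np.average(ecc[sel], weights=area[sel]))
        keep_e.append(e_samp)
        keep_m.append(np.sqrt(areal))
        keep_n.append(n)

    if not keep_e:
        raise ValueError("all moving-ring windows are empty")
    order = np.argsort(keep_e)
    e_arr = np.asarray(keep_e)[order]
    m_arr = np.asarray(keep_m)[order]
    # strictly increasing sample positions: merge duplicates by averaging
    uniq, inv = np.unique(np.round(e_arr, 9), return_inverse=True)
    m_u = np.bincount(inv, weights=m_arr) / np.bincount(inv)
    n_u = np.bincount(inv, weights=np.asarray([n for n in keep_n if n > 0], float)[order])
    return EmpiricalCMFSamples(uniq, m_u, w, n_u.astype(int))


@dataclass
class CMFFit:
    """Result of fitting M(E) = A/(E+E2) to empirical linear-CMF samples."""

    mapping: CorticalMapping
    residual_norm: float
    ci95_A: tuple = field(default=(np.nan, np.nan))
    ci95_E2: tuple = field(default=(np.nan, np.nan))

    def to_dict(self) -> dict:
        d = self.mapping.to_dict()
        d.update(residual_norm=self.residual_norm,
                 ci95_A=list(self.ci95_A), ci95_E2=list(self.ci95_E2))
        return d


def fit_cmf(samples: EmpiricalCMFSamples, weight_by_count: bool = False) -> CMFFit:
    """Least-squares fit of the hyperbolic linear CMF to moving-ring samples.

    Returns the fitted :class:`CorticalMapping` (A, E2, M0 = A/E2) together
    with the residual norm and 95% confidence intervals from the covariance
    of the fit.  Requires at least 5 samples spanning at least 2 deg.
    """
    e = samples.eccentricity_deg
    m = samples.linear_cmf_mm_per_deg
    if len(e) < 5:
        raise ValueError("need at least 5 CMF samples to fit")
    if e.max() - e.min() < 2.0:
        raise ValueError("CMF samples must span at least 2 deg of eccentricity")

    def model(E, A, E2):
        return A / (E + E2)

    sigma = None
    if weight_by_count:
        n = np.maximum(samples.n_units_per_ring.astype(float), 1.0)
        sigma = 1.0 / np.sqrt(n[: len(e)])
    p0 = (m[0] * (e[0] + 1.0), 1.0)
    try:
        popt, pcov = curve_fit(model, e, m, p0=p0, sigma=sigma, maxfev=10000)
    except RuntimeError as err:  # pragma: no cover - pathological inputs
        raise RuntimeError(f"CMF fit did not converge: {err}") from err
    A_hat, E2_hat = float(popt[0]), float(popt[1])
    if A_hat <= 0 or E2_hat <= 0:
        raise RuntimeError(f"CMF fit converged to invalid parameters A={A_hat}, E2={E2_hat}")
    resid = m - model(e, *popt)
    se = np.sqrt(np.diag(pcov))
    return CMFFit(
        mapping=CorticalMapping(M0=A_hat / E2_hat, E2=E2_hat),
        residual_norm=float(np.linalg.norm(resid)),
        ci95_A=(A_hat - 1.96 * se[0], A_hat + 1.96 * se[0]),
        ci95_E2=(E2_hat - 1.96 * se[1], E2_hat + 1.96 * se[1]),
    )


# ---------------------------------------------------------------------------
# table I/O

PRF_TABLE_COLUMNS = ["id", "x_deg", "y_deg", "sigma_deg", "ve", "area_mm2"]


def write_prf_table(df: pd.DataFrame, path) -> None:
    """Write a pRF parameter table as CSV (id, x_deg, y_deg, sigma_deg, ve, area_mm2)."""
    out = pd.DataFrame({
        "id": df.get("id", pd.RangeIndex(len(df))),
        "x_deg": df["x"],
        "y_deg": df["y"],
        "sigma_deg": df["sigma"],
        "ve": df["ve"],
        "area_mm2": df.get("area_mm2", np.nan),
    })
    out.to_csv(path, index=False)


def read_prf_table(path) -> pd.DataFrame:
    """Read a pRF parameter table written by :func:`write_prf_table`."""
    df = pd.read_csv(path)
    return pd.DataFrame({
        "id": df["id"],
        "x": df["x_deg"],
        "y": df["y_deg"],
        "sigma": df["sigma_deg"],
        "ve": df["ve"],
        "area_mm2": df["area_mm2"],
    })
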