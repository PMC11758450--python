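"""Single-Gaussian pRF estimation with a coarse-to-fine search.

The model time series of a candidate pRF (x, y, sigma) is the stimulus
aperture weighted by a unit-height isotropic Gaussian, convolved with the
HRF; gain and baseline enter by closed-form least squares, so the goodness
of a candidate reduces to the squared correlation between the demeaned data
and the demeaned prediction.  The coarse stage exhaustively evaluates a
lattice of centers crossed with log-spaced sizes; the fine stage polishes
the coarse winner with a derivative-free Nelder-Mead search over
(x, y, log sigma), run simultaneously for all units of a dataset in
vectorized batches.  Everything is deterministic given its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import HRFSpec, PRFParams, convolve_hrf
from .stimulus import StimulusSequence

logger = logging.getLogger(__name__)

__all__ = ["GridSpec", "FitResult", "PRFFitter", "fit_prf", "fit_dataset",
           "variance_explained"]


@dataclass(frozen=True)
class GridSpec:
    """Search-space configuration for the coarse-to-fine fit.

    The coarse lattice covers ``extent_factor`` times the stimulus radius in
    steps of ``x_step`` deg, crossed with ``n_sigma`` log-spaced sizes in
    [sigma_min, sigma_max].  ``nm_*`` control the fine-stage Nelder-Mead
    iteration budget and termination tolerances.
    """

    x_step: float = 0.5
    extent_factor: float = 1.1
    sigma_min: float = 0.25
    sigma_max: float = 4.0
    n_sigma: int = 12
    nm_iterations: int = 120
    nm_xatol: float = 1e-3
    nm_fatol: float = 1e-9


#: lighter search used by the desk-scale phantom experiments
EXPERIMENT_GRID = GridSpec(x_step=1.0, sigma_min=0.3, sigma_max=3.2, n_sigma=6,
                           nm_iterations=60, nm_xatol=5e-3, nm_fatol=1e-8)


@dataclass
class FitResult:
    """Outcome of fitting one unit: best pRF, gain, residual, coarse winner."""

    prf: PRFParams
    amplitude: float
    rss: float
    grid_best: PRFParams


def variance_explained(ts: np.ndarray, model_ts: np.ndarray) -> float:
    """1 - sum((ts - model)^2) / sum((ts - mean(ts))^2)."""
    ts = np.asarray(ts, float)
    model_ts = np.asarray(model_ts, float)
    if ts.shape != model_ts.shape:
        raise ValueError("time series must have equal lengths")
    tot = np.sum((ts - ts.mean()) ** 2)
    if tot == 0:
        raise ValueError("variance explained undefined for a constant time series")
    return float(1.0 - np.sum((ts - model_ts) ** 2) / tot)


class PRFFitter:
    """Precomputed fitting engine for one (stimulus, HRF, grid) combination.

    Precomputes the HRF-convolved, time-demeaned pixel design matrix and the
    normalized predictions of every coarse-grid candidate; instances are
    cached by stimulus content so repeated :func:`fit_dataset` calls on the
    same design pay the setup cost once.
    """

    def __init__(self, stim: StimulusSequence, hrf: HRFSpec, grid: GridSpec):
        if abs(stim.tr_s - hrf.tr_s) > 1e-9:
            raise ValueError("stimulus and HRF must share the same TR")
        self.stim, self.hrf, self.grid = stim, hrf, grid
        S = stim.frames.reshape(stim.n_frames, -1).astype(float)
        S_conv = convolve_hrf(S, hrf)
        self.Sc = S_conv - S_conv.mean(axis=0)  # (T, P), demeaned predictions
        X, Y = stim.pixel_centers()
        self._px = X.ravel()
        self._py = Y.ravel()

        ext = grid.extent_factor * stim.extent_deg
        pos = np.arange(-ext, ext + 1e-9, grid.x_step)
        sig = np.geomspace(grid.sigma_min, grid.sigma_max, grid.n_sigma)
        gx, gy, gs = (a.ravel() for a in np.meshgrid(pos, pos, sig, indexing="ij"))
        # deterministic tie-break: order candidates by (sigma, eccentricity)
        # so the first maximum is the smallest sigma, then smallest ecc
        order = np.lexsort((np.hypot(gx, gy), gs))
        self.gx, self.gy, self.gs = gx[order], gy[order], gs[order]
        Yg = self.Sc @ self._gauss(self.gx, self.gy, self.gs).T  # (T, G)
        norms = np.linalg.norm(Yg, axis=0)
        norms[norms < 1e-12] = np.inf
        self.Yn = Yg / norms

    # -- model pieces -----------------------------------------------------

    def _gauss(self, x, y, s) -> np.ndarray:
        x = np.asarray(x, float)[:, None]
        y = np.asarray(y, float)[:, None]
        s = np.asarray(s, float)[:, None]
        return np.exp(-((self._px[None, :] - x) ** 2 + (self._py[None, :] - y) ** 2)
                      / (2.0 * s**2))

    def predict(self, x, y, s) -> np.ndarray:
        """Demeaned model predictions for candidates, (T, k)."""
        return self.Sc @ self._gauss(x, y, s).T

    # -- fitting ----------------------------------------------------------

    def fit_batch(self, ts_mat: np.ndarray) -> pd.DataFrame:
        """Fit every row of (n_units, T); invalid rows are flagged, not fatal."""
        ts_mat = np.asarray(ts_mat, float)
        n, T = ts_mat.shape
        if T != self.stim.n_frames:
            raise ValueError("time series length does not match the stimulus")
        finite = np.isfinite(ts_mat).all(axis=1)
        tsc = np.where(finite[:, None], ts_mat, 0.0)
        tsc = tsc - tsc.mean(axis=1, keepdims=True)
        tnorm = np.linalg.norm(tsc, axis=1)
        ok = finite & (tnorm > 0)
        tn = np.zeros_like(tsc)
        tn[ok] = tsc[ok] / tnorm[ok, None]

        # coarse stage: best positive-gain correlation over the lattice
        best_idx = np.empty(n, dtype=int)
        best_corr = np.empty(n)
        chunk = max(1, int(2**24 // max(self.Yn.shape[1], 1)))
        for lo in range(0, n, chunk):
            C = tn[lo:lo + chunk] @ self.Yn
            best_idx[lo:lo + chunk] = np.argmax(C, axis=1)
            best_corr[lo:lo + chunk] = np.take_along_axis(
                C, best_idx[lo:lo + chunk, None], axis=1)[:, 0]
        gx0, gy0 = self.gx[best_idx], self.gy[best_idx]
        gs0 = self.gs[best_idx]
        f_coarse = 1.0 - np.clip(best_corr, 0.0, None) ** 2

        # fine stage: batched Nelder-Mead on (x, y, log sigma)
        def objective(rows, pts):
            pred = self.predict(pts[:, 0], pts[:, 1], np.exp(pts[:, 2]))
            pn = np.linalg.norm(pred, axis=0)
            pn[pn < 1e-12] = np.inf
            corr = np.einsum("kt,tk->k", tn[rows], pred / pn)
            return 1.0 - np.clip(corr, 0.0, None) ** 2

        x0 = np.column_stack([gx0, gy0, np.log(gs0)])
        xf, ff = _batched_nelder_mead(
            objective, x0, rows_mask=ok, n_iter=self.grid.nm_iterations,
            xatol=self.grid.nm_xatol, fatol=self.grid.nm_fatol)

        # keep the better of the two stages (they rarely disagree)
        use_coarse = f_coarse < ff
        xf[use_coarse] = x0[use_coarse]
        ff[use_coarse] = f_coarse[use_coarse]

        fx, fy, fs = xf[:, 0], xf[:, 1], np.exp(xf[:, 2])
        ve = np.clip(1.0 - ff, 0.0, 1.0)
        # gain and rss at the winning parameters
        pred = self.predict(fx, fy, fs)
        pp = np.einsum("tk,tk->k", pred, pred)
        pp[pp < 1e-24] = np.inf
        amplitude = np.einsum("kt,tk->k", tsc, pred) / pp
        rss = tnorm**2 * (1.0 - ve)

        out = pd.DataFrame({
            "x": fx, "y": fy, "sigma": fs, "ve": ve, "amplitude": amplitude,
            "rss": rss, "grid_x": gx0, "grid_y": gy0, "grid_sigma": gs0,
            "ok": ok,
        })
        bad = ~ok
        out.loc[bad, ["x", "y", "sigma", "amplitude"]] = np.nan
        out.loc[bad, "ve"] = 0.0
        return out


_FITTER_CACHE: dict = {}


def get_fitter(stim: StimulusSequence, hrf: HRFSpec,
               grid: GridSpec | None = None) -> PRFFitter:
    grid = grid or GridSpec()
    key = (stim.fingerprint(), hrf, grid)
    if key not in _FITTER_CACHE:
        if len(_FITTER_CACHE) > 8:  # bound memory across many test designs
            _FITTER_CACHE.clear()
        _FITTER_CACHE[key] = PRFFitter(stim, hrf, grid)
    return _FITTER_CACHE[key]


def fit_prf(ts: np.ndarray, stim: StimulusSequence, hrf: HRFSpec,
            grid_spec: GridSpec | None = None) -> FitResult:
    """Fit a single time series; raises on constant or non-finite input."""
    ts = np.asarray(ts, float)
    if ts.ndim != 1:
        raise ValueError("fit_prf expects a 1-D time series")
    if not np.isfinite(ts).all():
        raise ValueError("time series contains non-finite values")
    if np.ptp(ts) == 0:
        raise ValueError("cannot fit a constant time series")
    fitter = get_fitter(stim, hrf, grid_spec)
    row = fitter.fit_batch(ts[None, :]).iloc[0]
    return FitResult(
        prf=PRFParams(row["x"], row["y"], row["sigma"], float(np.clip(row["ve"], 0, 1))),
        amplitude=float(row["amplitude"]),
        rss=float(row["rss"]),
        grid_best=PRFParams(row["grid_x"], row["grid_y"], row["grid_sigma"]),
    )


def fit_dataset(dataset, stim: StimulusSequence, hrf: HRFSpec,
                grid_spec: GridSpec | None = None, n_workers: int = 1) -> pd.DataFrame:
    """Fit every unit of a phantom or surface dataset (or an (n, T) array).

    Per-unit failures (constant or non-finite series) are recorded with
    ``ok=False`` and ve 0 rather than raised.  Fits are independent across
    units, so results do not depend on unit order.  ``n_workers`` is accepted
    for interface stability; the vectorized engine runs single-threaded.
    """
    if hasattr(dataset, "unit_timeseries"):
        ts_mat = dataset.unit_timeseries()
    else:
        ts_mat = np.asarray(dataset, float)
    fitter = get_fitter(stim, hrf, grid_spec)
    logger.info("fitting %d units x %d frames", ts_mat.shape[0], ts_mat.shape[1])
    out = fitter.fit_batch(ts_mat)
    out.insert(0, "id", np.arange(len(out)))
    return out


# ---------------------------------------------------------------------------
# batched Nelder-Mead


def _batched_nelder_mead(objective, x0: np.ndarray, rows_mask=None,
                         n_iter: int = 120, xatol: float = 1e-3,
                         fatol: float = 1e-9,
                         init_step=(0.4, 0.4, 0.3)):
    """Minimize ``objective`` independently for every row of ``x0``.

    ``objective(rows, pts)`` evaluates points ``pts[k]`` belonging to batch
    rows ``rows[k]`` and must be vectorized over k.  Standard Nelder-Mead
    (reflection/expansion/contraction/shrink with coefficients 1, 2, 0.5,
    0.5); rows whose simplex has collapsed below the tolerances are frozen
    and cost nothing.  Fully deterministic.
    """
    V, D = x0.shape
    if rows_mask is None:
        rows_mask = np.ones(V, bool)
    simplex = np.repeat(x0[:, None, :], D + 1, axis=1)
    for d in range(D):
        simplex[:, d + 1, d] += init_step[d]
    fvals = np.full((V, D + 1), np.inf)
    all_rows = np.where(rows_mask)[0]
    for j in range(D + 1):
        fvals[all_rows, j] = objective(all_rows, simplex[all_rows, j])

    active = rows_mask.copy()
    for _ in range(n_iter):
        order = np.argsort(fvals, axis=1, kind="stable")
        simplex = np.take_along_axis(simplex, order[:, :, None], axis=1)
        fvals = np.take_along_axis(fvals, order, axis=1)
        with np.errstate(invalid="ignore"):
            conv = (fvals[:, -1] - fvals[:, 0] <= fatol) & \
                (np.ptp(simplex, axis=1).max(axis=1) <= xatol)
        active &= ~conv
        rows = np.where(active)[0]
        if rows.size == 0:
            break

        worst = simplex[rows, -1]
        centroid = simplex[rows, :-1].mean(axis=1)
        xr = centroid + (centroid - worst)
        fr = objective(rows, xr)
        f0 = fvals[rows, 0]
        f_second = fvals[rows, -2]
        fw = fvals[rows, -1]

        expand = fr < f0
        out_con = (fr >= f_second) & (fr < fw)
        in_con = fr >= fw
        cand = np.where(
            expand[:, None], centroid + 2.0 * (xr - centroid),
            np.where(out_con[:, None], centroid + 0.5 * (xr - centroid),
                     centroid - 0.5 * (centroid - worst)))
        fc = objective(rows, cand)

        take_cand = (expand & (fc < fr)) | (out_con & (fc <= fr)) | (in_con & (fc < fw))
        shrink = (out_con & (fc > fr)) | (in_con & (fc >= fw))
        take_refl = ~take_cand & ~shrink

        new_x = np.where(take_cand[:, None], cand, xr)
        new_f = np.where(take_cand, fc, fr)
        ns = take_cand | take_refl
        simplex[rows[ns], -1] = new_x[ns]
        fvals[rows[ns], -1] = new_f[ns]
        if shrink.any():
            rs = rows[shrink]
            b = simplex[rs, 0][:, None, :]
            simplex[rs, 1:] = b + 0.5 * (simplex[rs, 1:] - b)
            for j in range(1, D + 1):
                fvals[rs, j] = objective(rs, simplex[rs, j])

    order = np.argsort(fvals, axis=1, kind="stable")
    simplex = np.take_along_axis(simplex, order[:, :, None], axis=1)
    fvals = np.take_along_axis(fvals, order, axis=1)
    return simplex[:, 0].copy(), fvals[:, 0].copy()
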