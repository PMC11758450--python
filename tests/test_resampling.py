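"""Resampling transforms: interpolation contracts, projection, subsampling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from prfbias.fitting import EXPERIMENT_GRID, fit_dataset
from prfbias.phantom import PhantomDataset, build_slab, simulate_subject
from prfbias.resampling import (ResampleSpec, project_parameters,
                                project_to_surface, subsample_units,
                                substitute_noiseless, upsample_volume)


def _dataset_from_volume(vol4d, voxel_mm=2.0):
    return PhantomDataset(bold=vol4d, voxel_mm=voxel_mm, truth=None,
                          geometry={}, cnr=np.inf)


@pytest.fixture(scope="module")
def noiseless_subject(mapping, run_stim, run_hrf):
    slab = build_slab(mapping)
    return slab, simulate_subject(slab, run_stim, run_hrf, cnr=np.inf)


class TestUpsample:
    def test_constant_volume_stays_constant(self):
        ds = _dataset_from_volume(np.full((4, 5, 3, 6), 3.25))
        up = upsample_volume(ds, 1.0)
        assert np.allclose(up.bold, 3.25)
        assert up.bold.shape == (7, 9, 5, 6)
        assert up.truth is None

    def test_trilinear_preserves_node_values(self):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal((4, 4, 3, 5))
        up = upsample_volume(_dataset_from_volume(vol), 1.0)
        assert np.allclose(up.bold[::2, ::2, ::2], vol)

    def test_trilinear_reproduces_affine_fields(self):
        """Trilinear interpolation is exact on v = 3x + 2y - z + 1."""
        i, j, k = np.meshgrid(np.arange(5), np.arange(6), np.arange(4),
                              indexing="ij")
        vol = (3.0 * i + 2.0 * j - 1.0 * k + 1.0)[..., None]
        up = upsample_volume(_dataset_from_volume(vol), 0.5)
        ii, jj, kk = np.meshgrid(np.arange(0, 4.01, 0.25),
                                 np.arange(0, 5.01, 0.25),
                                 np.arange(0, 3.01, 0.25), indexing="ij")
        expected = 3.0 * ii + 2.0 * jj - kk + 1.0
        assert np.abs(up.bold[..., 0] - expected).max() < 1e-9

    def test_nearest_returns_source_values(self):
        rng = np.random.default_rng(1)
        vol = rng.standard_normal((4, 4, 3, 2))
        up = upsample_volume(_dataset_from_volume(vol), 1.0, "nearest")
        assert np.isin(up.bold, vol).all()

    def test_coarser_target_rejected(self):
        ds = _dataset_from_volume(np.zeros((4, 4, 3, 2)))
        with pytest.raises(ValueError):
            upsample_volume(ds, 4.0)


class TestProjectToSurface:
    def test_constant_volume_projects_to_constant(self):
        ds = _dataset_from_volume(np.full((6, 7, 3, 4), 1.5))
        surf = project_to_surface(ds, vertex_spacing_mm=0.95)
        assert np.allclose(surf.bold, 1.5)

    def test_depth_average_is_identity_on_columns(self, noiseless_subject):
        """Columns constant across depth survive depth averaging unchanged."""
        _, ds = noiseless_subject
        surf = project_to_surface(ds, vertex_spacing_mm=2.0)
        # vertices at voxel centers (spacing = voxel size) reproduce columns
        nx, ny = ds.bold.shape[:2]
        assert np.allclose(surf.bold.reshape(nx, ny, -1), ds.bold[:, :, 0], atol=1e-9)

    def test_vertex_density_ratio_near_default(self, noiseless_subject):
        _, ds = noiseless_subject
        surf = project_to_surface(ds, vertex_spacing_mm=0.95)
        ratio = surf.n_units / np.prod(ds.bold.shape[:2])
        assert ratio == pytest.approx((2.0 / 0.95) ** 2, rel=0.10)

    def test_single_depth_rejected(self):
        ds = _dataset_from_volume(np.zeros((4, 4, 1, 2)))
        with pytest.raises(ValueError):
            project_to_surface(ds)

    def test_nearest_vertices_copy_voxel_series(self, noiseless_subject):
        _, ds = noiseless_subject
        surf = project_to_surface(ds, interpolation="nearest")
        flat = ds.bold.reshape(-1, ds.bold.shape[3])
        sample = surf.bold[:: max(1, surf.n_units // 50)]
        for row in sample:
            assert (np.abs(flat - row).max(axis=1) < 1e-12).any()


class TestSigmaInflation:
    def test_trilinear_broadens_sigma_nearest_does_not(self, mapping, run_stim,
                                                       run_hrf, noiseless_subject):
        """Time-series mixing inflates fitted sizes; nearest projection does not."""
        _, ds = noiseless_subject
        deltas = {}
        for kind in ("trilinear", "nearest"):
            surf = project_to_surface(ds, interpolation=kind)
            fits = fit_dataset(surf, run_stim, run_hrf, EXPERIMENT_GRID)
            rel = fits.sigma / surf.truth.sigma.to_numpy() - 1
            deltas[kind] = np.median(rel)
        assert abs(deltas["nearest"]) < 0.02
        assert deltas["trilinear"] > deltas["nearest"]


class TestSubsample:
    @pytest.fixture(scope="class")
    def table(self):
        rng = np.random.default_rng(0)
        return pd.DataFrame({"x": rng.normal(0, 2, 2000),
                             "y": rng.normal(0, 2, 2000),
                             "sigma": 1.0, "ve": 1.0})

    def test_full_subsample_is_identity(self, table):
        sub = subsample_units(table, len(table), seed=0)
        assert len(sub) == len(table)
        assert set(map(tuple, sub[["x", "y"]].to_numpy())) == \
            set(map(tuple, table[["x", "y"]].to_numpy()))

    def test_seeded_reproducibility(self, table):
        a = subsample_units(table, 500, seed=4)
        b = subsample_units(table, 500, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_subset_preserves_eccentricity_distribution(self, table):
        """Random subsets are distributionally indistinguishable from the full set."""
        ecc = np.hypot(table.x, table.y)
        ok = 0
        for seed in range(100):
            sub = subsample_units(table, 500, seed=seed)
            p = ks_2samp(np.hypot(sub.x, sub.y), ecc).pvalue
            ok += p > 0.01
        assert ok >= 95

    def test_invalid_sizes_rejected(self, table):
        with pytest.raises(ValueError):
            subsample_units(table, 0, seed=0)
        with pytest.raises(ValueError):
            subsample_units(table, len(table) + 1, seed=0)


class TestSubstituteNoiseless:
    def test_refit_recovers_substituting_parameters(self, mapping, run_stim, run_hrf):
        slab = build_slab(mapping, n_polar=6)
        noisy = simulate_subject(slab, run_stim, run_hrf, cnr=2.0, seed=0)
        fits = fit_dataset(noisy, run_stim, run_hrf, EXPERIMENT_GRID)
        clean = substitute_noiseless(noisy, fits, run_stim, run_hrf)
        assert np.isinf(clean.cnr)
        refits = fit_dataset(clean, run_stim, run_hrf, EXPERIMENT_GRID)
        assert refits.ve.median() >= 0.999
        assert np.median(np.hypot(refits.x - fits.x, refits.y - fits.y)) < 0.05

    def test_idempotent(self, mapping, run_stim, run_hrf):
        slab = build_slab(mapping, n_polar=4)
        noisy = simulate_subject(slab, run_stim, run_hrf, cnr=2.0, seed=1)
        fits = fit_dataset(noisy, run_stim, run_hrf, EXPERIMENT_GRID)
        once = substitute_noiseless(noisy, fits, run_stim, run_hrf)
        twice = substitute_noiseless(once, fits, run_stim, run_hrf)
        assert np.array_equal(once.bold, twice.bold)

    def test_failed_fits_zeroed_and_flagged(self, mapping, run_stim, run_hrf):
        slab = build_slab(mapping, n_polar=4)
        noisy = simulate_subject(slab, run_stim, run_hrf, cnr=2.0, seed=2)
        fits = fit_dataset(noisy, run_stim, run_hrf, EXPERIMENT_GRID)
        fits.loc[0, "ok"] = False
        out = substitute_noiseless(noisy, fits, run_stim, run_hrf)
        assert np.allclose(out.bold.reshape(-1, out.n_frames)[0], 0.0)
        assert not out.flags.ravel()[0]


class TestProjectParameters:
    def test_constant_fields_stay_constant(self, noiseless_subject, run_stim,
                                           run_hrf):
        _, ds = noiseless_subject
        n = np.prod(ds.bold.shape[:3])
        fits = pd.DataFrame({"x": np.full(n, 1.0), "y": np.full(n, -2.0),
                             "sigma": np.full(n, 0.9), "ve": np.full(n, 0.8)})
        out = project_parameters(ds, fits)
        assert np.allclose(out.x, 1.0) and np.allclose(out.sigma, 0.9)

    def test_nearest_copies_some_voxel_value(self, noiseless_subject):
        """Depth-column-structured parameter maps: nearest projection copies values."""
        _, ds = noiseless_subject
        nx, ny, nz = ds.bold.shape[:3]
        rng = np.random.default_rng(0)
        col = rng.uniform(0.5, 2, (nx, ny, 1))
        sigma = np.broadcast_to(col, (nx, ny, nz)).ravel()
        fits = pd.DataFrame({"x": sigma, "y": sigma, "sigma": sigma,
                             "ve": np.ones(sigma.size)})
        out = project_parameters(ds, fits, interpolation="nearest")
        assert np.isin(np.round(out.sigma, 12), np.round(sigma, 12)).all()

    def test_wrong_table_length_rejected(self, noiseless_subject):
        _, ds = noiseless_subject
        with pytest.raises(ValueError):
            project_parameters(ds, pd.DataFrame({"x": [1.0], "y": [0.0],
                                                 "sigma": [1.0], "ve": [1.0]}))


def test_resample_spec_validation():
    spec = ResampleSpec(kind="vol2surf", depth_fractions=(0.0, 0.5, 1.0))
    assert spec.to_dict()["kind"] == "vol2surf"
    with pytest.raises(ValueError):
        ResampleSpec(kind="bogus")
    with pytest.raises(ValueError):
        ResampleSpec(kind="vol2vol", interpolation="cubic")
    with pytest.raises(ValueError):
        ResampleSpec(kind="vol2surf", depth_fractions=(1.0, 0.0))
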