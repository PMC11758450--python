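"""Phantom generator: slab geometry, forward model, noise, populations."""

import numpy as np
import pandas as pd
import pytest

from prfbias.clf import clf_distance
from prfbias.phantom import (HRFSpec, PRFParams, add_noise, build_slab,
                             load_phantom, prf_timecourse, prf_timecourses,
                             save_phantom, simulate_prf_population,
                             simulate_subject)
from prfbias.phantom import _gaussian_images


class TestSlab:
    def test_distance_axis_length(self, mapping):
        slab = build_slab(mapping, max_ecc_deg=7.8, voxel_mm=2.0)
        expected = int(np.ceil(clf_distance(7.8, mapping) / 2.0))
        assert slab.shape[0] == expected == 19

    def test_origin_column_is_foveal(self, mapping):
        slab = build_slab(mapping)
        assert slab.truth.loc[slab.truth.d_mm == 0, "ecc"].max() == 0.0

    def test_truth_follows_location_function(self, mapping):
        from prfbias.clf import clf_eccentricity
        slab = build_slab(mapping, d_offset_mm=0.7)
        assert np.allclose(slab.truth.ecc,
                           clf_eccentricity(slab.truth.d_mm.to_numpy(), mapping))
        assert np.allclose(slab.truth.sigma, 0.5 + 0.1 * slab.truth.ecc)

    def test_center_density_decreases_with_eccentricity(self, mapping):
        """Cortical magnification concentrates ground-truth centers foveally."""
        slab = build_slab(mapping, voxel_mm=0.5)
        counts, _ = np.histogram(slab.truth.ecc, bins=np.arange(0, 8))
        assert np.all(np.diff(counts) <= 0)
        assert counts[0] > counts[-1]

    def test_column_areas_tile_the_hemifield(self, mapping):
        """Summed column areas equal the model area of the covered sector."""
        from prfbias.clf import cortical_patch_area
        slab = build_slab(mapping, polar_span_deg=180.0)
        e_max = slab.truth.ecc.max()
        from prfbias.clf import clf_eccentricity
        e_hi = clf_eccentricity(slab.truth.d_mm.max() + 1.0, mapping)
        expected = cortical_patch_area(0.0, e_hi, np.pi, mapping)
        assert slab.truth.area_mm2.sum() == pytest.approx(expected, rel=1e-9)

    def test_too_small_slab_rejected(self, mapping):
        with pytest.raises(ValueError):
            build_slab(mapping, max_ecc_deg=0.2)
        with pytest.raises(ValueError):
            build_slab(mapping, n_polar=2)


class TestForwardModel:
    def test_zero_stimulus_gives_zero_response(self, small_stim, small_hrf):
        from prfbias.stimulus import StimulusSequence
        blank = StimulusSequence(frames=np.zeros_like(small_stim.frames),
                                 extent_deg=small_stim.extent_deg,
                                 deg_per_pixel=small_stim.deg_per_pixel,
                                 tr_s=small_stim.tr_s)
        ts = prf_timecourse(PRFParams(0, 0, 1.0), blank, small_hrf)
        assert np.allclose(ts, 0.0)

    def test_distant_prf_is_silent(self, small_stim, small_hrf):
        ts = prf_timecourse(PRFParams(50.0, 0.0, 1.0), small_stim, small_hrf,
                            amplitude=1.0)
        assert np.abs(ts).max() < 1e-6

    def test_amplitude_linearity(self, small_stim, small_hrf):
        prf = PRFParams(2.0, -1.0, 1.0)
        one = prf_timecourse(prf, small_stim, small_hrf, amplitude=1.0)
        three = prf_timecourse(prf, small_stim, small_hrf, amplitude=3.0)
        assert np.allclose(three, 3.0 * one)

    def test_gaussian_mass_matches_dense_quadrature(self, small_stim):
        """Pixel-summed Gaussian mass over the disc agrees with dense integration."""
        x0, y0, sig = 1.5, -0.5, 1.0
        R = small_stim.extent_deg
        X, Y = small_stim.pixel_centers()
        disc = (X**2 + Y**2 <= R**2).ravel()
        g = _gaussian_images([x0], [y0], [sig], small_stim)[0]
        coarse = (g * disc).sum() * small_stim.deg_per_pixel**2
        n = 1200
        c = np.linspace(-R, R, n)
        XX, YY = np.meshgrid(c, c)
        dense = np.exp(-((XX - x0) ** 2 + (YY - y0) ** 2) / (2 * sig**2))
        dense = dense[XX**2 + YY**2 <= R**2].sum() * (2 * R / (n - 1)) ** 2
        assert coarse == pytest.approx(dense, rel=0.01)

    def test_small_sigma_warns_about_aliasing(self, small_stim, small_hrf):
        df = pd.DataFrame({"x": [0.0], "y": [0.0], "sigma": [0.05]})
        with pytest.warns(RuntimeWarning):
            prf_timecourses(df, small_stim, small_hrf)

    def test_hrf_kernel_constraints(self):
        k = HRFSpec(tr_s=1.0).kernel()
        assert len(k) >= 20
        assert np.abs(k).max() == pytest.approx(1.0)
        with pytest.raises(ValueError):
            HRFSpec(duration_s=10.0)


class TestNoise:
    def test_infinite_cnr_is_identity(self):
        ts = np.sin(np.linspace(0, 10, 200))
        out = add_noise(ts, np.inf, seed=0)
        assert np.array_equal(out, ts)

    def test_seeded_reproducibility(self):
        ts = np.sin(np.linspace(0, 10, 200))
        assert np.array_equal(add_noise(ts, 2.0, seed=7), add_noise(ts, 2.0, seed=7))
        assert not np.array_equal(add_noise(ts, 2.0, seed=7),
                                  add_noise(ts, 2.0, seed=8))

    def test_noise_level_matches_cnr(self):
        ts = np.sin(np.linspace(0, 300, 10_000))
        noisy = add_noise(ts, 2.0, seed=3)
        ratio = (noisy - ts).std() / ts.std()
        assert ratio == pytest.approx(0.5, rel=0.05)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.ones(50), 2.0, seed=0)

    def test_invalid_cnr_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.sin(np.arange(50.0)), -1.0, seed=0)


class TestSubjects:
    def test_same_seed_identical(self, mapping, small_stim, small_hrf):
        slab = build_slab(mapping, n_polar=4, depth_voxels=2)
        a = simulate_subject(slab, small_stim, small_hrf, cnr=2.0, seed=5)
        b = simulate_subject(slab, small_stim, small_hrf, cnr=2.0, seed=5)
        assert np.array_equal(a.bold, b.bold)

    def test_distinct_seeds_share_truth(self, mapping, small_stim, small_hrf):
        slab = build_slab(mapping, n_polar=4, depth_voxels=2)
        a = simulate_subject(slab, small_stim, small_hrf, cnr=2.0, seed=1)
        b = simulate_subject(slab, small_stim, small_hrf, cnr=2.0, seed=2)
        assert not np.array_equal(a.bold, b.bold)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_noiseless_depth_columns_identical(self, mapping, small_stim, small_hrf):
        slab = build_slab(mapping, n_polar=4, depth_voxels=3)
        ds = simulate_subject(slab, small_stim, small_hrf, cnr=np.inf)
        assert np.array_equal(ds.bold[:, :, 0], ds.bold[:, :, 2])

    def test_phantom_nifti_roundtrip(self, tmp_path, mapping, small_stim, small_hrf):
        slab = build_slab(mapping, n_polar=4, depth_voxels=2)
        ds = simulate_subject(slab, small_stim, small_hrf, cnr=4.0, seed=9)
        save_phantom(ds, tmp_path / "ph.nii.gz")
        back = load_phantom(tmp_path / "ph.nii.gz")
        assert np.allclose(back.bold, ds.bold, atol=1e-6)
        assert back.voxel_mm == ds.voxel_mm
        assert back.geometry["hemifield"] == "right"


class TestPopulations:
    def test_centers_concentrate_at_fixation(self):
        pop = simulate_prf_population(100_000, center_spread_deg=2.0,
                                      sigma_deg=1.0, seed=0)
        assert abs(pop.x.mean()) < 0.05
        assert abs(pop.y.mean()) < 0.05
        assert pop.x.std() == pytest.approx(2.0, rel=0.02)

    def test_degenerate_spread_collapses_to_fovea(self):
        pop = simulate_prf_population(50, center_spread_deg=1e-9, sigma_deg=1.0,
                                      seed=0)
        assert np.abs(pop[["x", "y"]].to_numpy()).max() < 1e-6

    def test_seed_reproducibility(self):
        a = simulate_prf_population(100, 2.0, 1.0, seed=3)
        b = simulate_prf_population(100, 2.0, 1.0, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_prf_population(0, 2.0, 1.0)
        with pytest.raises(ValueError):
            simulate_prf_population(10, -1.0, 1.0)


def test_prfparams_validation():
    with pytest.raises(ValueError):
        PRFParams(0, 0, -1.0)
    with pytest.raises(ValueError):
        PRFParams(0, 0, 1.0, ve=1.5)
    assert PRFParams(3.0, 4.0, 1.0).eccentricity == pytest.approx(5.0)
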