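"""Phantom geometry, signal simulation and cohort generation."""

import numpy as np
import pytest

from t1rho import (GeometryError, GridSpec, InvalidParameterError, PhantomSpec,
                   SpinLockProtocol, TissueRelaxation, anatomical_grid,
                   build_phantom, correct_series, generate_cohort, mz_over_m0,
                   simulate_series, t1rho_grid)
from t1rho.phantom import (BRAIN, TUMOUR, CohortDesign, label_areas_mm2,
                           roi_masks_from_labels)
from t1rho.relaxation import DecayCurve


class TestBuildPhantom:
    def test_zero_radius_means_no_tumour(self, tissue_params):
        spec = PhantomSpec(grid=t1rho_grid(), tumour_radius_mm=0.0,
                           tissue_params=tissue_params)
        gt = build_phantom(spec)
        assert (gt.label_map == TUMOUR).sum() == 0
        spec2 = PhantomSpec(grid=t1rho_grid(), tumour_radius_mm=1.3,
                            tissue_params=tissue_params)
        gt2 = build_phantom(spec2)
        np.testing.assert_array_equal(gt.label_map != 0, gt2.label_map != 0)

    def test_brain_area_matches_study_roi_size(self, tissue_params):
        """Central-slice brain area within the observed 18 +/- 2 mm^2."""
        spec = PhantomSpec(grid=anatomical_grid(), tissue_params=tissue_params)
        gt = build_phantom(spec)
        areas = label_areas_mm2(gt.label_map, spec.grid, BRAIN)
        for k in (3, 4, 5, 6):  # the four central slices
            assert 16.0 <= areas[k] <= 20.0

    def test_tumour_area_within_observed_range(self, tissue_params):
        spec = PhantomSpec(grid=anatomical_grid(), tumour_radius_mm=1.3,
                           tissue_params=tissue_params)
        gt = build_phantom(spec)
        areas = label_areas_mm2(gt.label_map, spec.grid, TUMOUR)
        nonzero = areas[areas > 0]
        assert nonzero.size >= 1
        assert np.all((nonzero >= 3.0) & (nonzero <= 23.0))

    def test_sphere_voxel_count_matches_brute_force(self, tissue_params):
        grid = t1rho_grid()
        spec = PhantomSpec(grid=grid, tumour_radius_mm=1.5,
                           tumour_center_mm=(0.5, 0.0, 0.0),
                           tissue_params=tissue_params)
        gt = build_phantom(spec)
        # exhaustive voxel-centre inclusion oracle
        count = 0
        for i, x in enumerate(grid.x_centers()):
            for j, y in enumerate(grid.y_centers()):
                for k, z in enumerate(grid.z_centers()):
                    if (x - 0.5) ** 2 + y ** 2 + z ** 2 <= 1.5 ** 2:
                        count += 1
        assert (gt.label_map == TUMOUR).sum() == count

    def test_tumour_outside_brain_rejected(self, tissue_params):
        spec = PhantomSpec(grid=t1rho_grid(), tumour_radius_mm=1.0,
                           tumour_center_mm=(2.4, 0.0, 0.0),
                           tissue_params=tissue_params)
        with pytest.raises(GeometryError):
            build_phantom(spec)

    def test_roi_masks_contralateral_and_disjoint(self, full_phantom):
        grid = full_phantom.grid
        roi = roi_masks_from_labels(full_phantom.label_map, grid)
        x = grid.x_centers()[:, None, None] * np.ones(grid.shape)
        assert np.all(x[roi == BRAIN] < 0)
        assert not np.any((roi == BRAIN) & (full_phantom.label_map == TUMOUR))


class TestSimulateSeries:
    def test_background_is_exactly_zero_noiseless(self, full_phantom, protocol):
        series = simulate_series(full_phantom, protocol, 1000.0,
                                 noise_model="none")
        bg = full_phantom.label_map == 0
        assert np.all(series.data[bg] == 0.0)

    def test_msat_forward_model_is_exactly_invertible(self, full_phantom,
                                                      protocol, tissue_params):
        series = simulate_series(full_phantom, protocol, 1000.0,
                                 noise_model="none", sat_model="msat")
        tsl = protocol.tsl_array()
        for name, lab in (("brain", BRAIN), ("tumour", TUMOUR)):
            p = tissue_params[name]
            idx = np.argwhere(full_phantom.label_map == lab)[0]
            curve = DecayCurve(tsl, series.data[tuple(idx)])
            corrected = correct_series(curve, p.t1_ms, p.t2_ms, protocol.tau_ms)
            ideal = p.s0 * np.exp(-tsl / p.t1rho_by_fsl_ms[1000.0])
            np.testing.assert_allclose(corrected.signal, ideal, rtol=1e-12)

    def test_saturation_magnitude_group1_brain(self, protocol):
        """At T1=669, T2=79, TSL=105 the steady-state factor is ~0.463."""
        tissue = {"brain": TissueRelaxation(669.0, 79.0, {100.0: 159.0}, 100.0)}
        gt = build_phantom(PhantomSpec(grid=GridSpec(34, 34, 1),
                                       tissue_params=tissue))
        series = simulate_series(gt, protocol, 100.0, noise_model="none")
        vox = tuple(np.argwhere(gt.label_map == BRAIN)[0])
        expected = 0.462813802 * 100.0 * np.exp(-105.0 / 159.0)
        assert series.data[vox][-1] == pytest.approx(expected, rel=1e-8)

    def test_rician_noise_floor(self, protocol):
        """With S0 = 0 the mean observed magnitude is sigma * sqrt(pi/2)."""
        tissue = {"brain": TissueRelaxation(669.0, 79.0, {100.0: 159.0},
                                            s0=1e-9)}
        gt = build_phantom(PhantomSpec(grid=GridSpec(40, 40, 4),
                                       tissue_params=tissue))
        gt.s0[:] = 0.0
        sigma = 2.0
        series = simulate_series(gt, protocol, 100.0, sigma=sigma, seed=3)
        n = series.data.size
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt(2 - np.pi / 2) / np.sqrt(n)
        assert abs(series.data.mean() - expected) < 4 * se

    def test_seed_determinism(self, full_phantom, protocol):
        a = simulate_series(full_phantom, protocol, 1000.0, sigma=2.0, seed=42)
        b = simulate_series(full_phantom, protocol, 1000.0, sigma=2.0, seed=42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unknown_fsl_and_bad_sigma(self, full_phantom, protocol):
        with pytest.raises(KeyError):
            simulate_series(full_phantom, protocol, 333.0)
        with pytest.raises(InvalidParameterError):
            simulate_series(full_phantom, protocol, 1000.0, sigma=-1.0)

    def test_t1rho_decay_saturation_biases_correction(self, protocol,
                                                      tissue_params):
        """When the saturation is driven by the spin-lock decay itself, the
        Msat-based correction over- or under-corrects and the fitted T1rho
        is biased (here the factor decays slower than Msat assumes, so the
        corrected signal decays too slowly -> bias high)."""
        from t1rho import fit_map
        gt = build_phantom(PhantomSpec(grid=GridSpec(34, 34, 1),
                                       tissue_params=tissue_params))
        series = simulate_series(gt, protocol, 1000.0, noise_model="none",
                                 sat_model="t1rho_decay")
        tmap = fit_map(series,
                       {k: v.t1_ms for k, v in tissue_params.items()},
                       {k: v.t2_ms for k, v in tissue_params.items()},
                       {"brain": gt.label_map == BRAIN,
                        "tumour": gt.label_map == TUMOUR})
        truth = tissue_params["brain"].t1rho_by_fsl_ms[1000.0]
        bias = tmap.t1rho_ms[gt.label_map == BRAIN] - truth
        assert np.all(bias != 0)
        assert np.all(np.sign(bias) == np.sign(bias.flat[0]))


class TestGenerateCohort:
    def test_pooled_measurement_counts(self, truth_cohort):
        """Weeks 2-4 tumour/brain counts: 0/15, 9/14, 7/12."""
        t = truth_cohort.truth_table
        pooled = t[(t.week.between(2, 4)) & (t.metric == "t1rho")
                   & (t.fsl == 1000.0)]
        counts = {g: ((pooled.group == g) & (pooled.roi == "tumour")).sum()
                  for g in (1, 2, 3)}
        brains = {g: ((pooled.group == g) & (pooled.roi == "brain")).sum()
                  for g in (1, 2, 3)}
        assert (counts[1], brains[1]) == (0, 15)
        assert (counts[2], brains[2]) == (9, 14)
        assert (counts[3], brains[3]) == (7, 12)

    def test_empty_design(self):
        design = CohortDesign().subset(mice=set())
        cohort = generate_cohort(design, seed=0)
        assert cohort.study_table.empty
        assert cohort.truth_table.empty
        assert cohort.measurements == []

    def test_drawn_brain_t1rho_mean_matches_configured(self):
        """Over 200 replicates the sample mean of drawn mutant-group brain
        T1rho at 1000 Hz stays within 3 standard errors of the 98 ms
        configured mean (SD 9 ms)."""
        design = CohortDesign().subset(mice={"g3m1", "g3m2"})
        vals = []
        for seed in range(200):
            t = generate_cohort(design, seed=seed, imaging=False).truth_table
            sel = (t.roi == "brain") & (t.fsl == 1000.0) & (t.metric == "t1rho")
            vals.extend(t.loc[sel, "value"])
        vals = np.asarray(vals)
        se = 9.0 / np.sqrt(vals.size)
        assert abs(vals.mean() - 98.0) < 3 * se

    def test_delta_model_reproduces_configured_delta_distribution(self):
        design = CohortDesign()
        vals = []
        for seed in range(60):
            t = generate_cohort(design, seed=seed, imaging=False).truth_table
            sel = (t.metric == "delta") & (t.fsl == 1000.0) & (t.group == 3)
            vals.extend(t.loc[sel, "value"])
        vals = np.asarray(vals)
        se = 13.0 / np.sqrt(vals.size)  # draws are independent at a single FSL
        assert abs(vals.mean() - 29.0) < 4 * se

    def test_seed_determinism_including_series(self):
        design = CohortDesign().subset(mice={"g3m2"}, weeks={3})
        a = generate_cohort(design, seed=7)
        b = generate_cohort(design, seed=7)
        assert a.truth_table.equals(b.truth_table)
        for ma, mb in zip(a.measurements, b.measurements):
            for f in ma.series:
                np.testing.assert_array_equal(ma.series[f].data,
                                              mb.series[f].data)

    def test_naive_group_cannot_bear_tumours(self):
        with pytest.raises(InvalidParameterError):
            CohortDesign(schedule=(("m", 1, 2, True),))
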