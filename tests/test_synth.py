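"""Synthetic generators: fields, cubes, masks, cohorts, history tables."""

import numpy as np
import pytest

from cspws.exceptions import PlacementError
from cspws.optics import ACFParams, forward_sigma
from cspws.synth import (CohortSpec, DensityField, GroupSpec, Cohort,
                         empirical_acf_radial, five_group_risk_spec,
                         gen_cohort, gen_density_field, gen_history_table,
                         gen_nucleus_image, gen_nucleus_masks,
                         simulate_spectral_cube, two_group_spec)
from cspws import risk as rk


class TestDensityField:
    def test_seed_determinism(self):
        p = ACFParams(d=2.4)
        a = gen_density_field(p, (16, 16, 80), (458, 458, 10), seed=7)
        b = gen_density_field(p, (16, 16, 80), (458, 458, 10), seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_variance_scales_with_sigma_n_sq(self):
        shape, vox = (24, 24, 80), (100.0, 100.0, 10.0)
        ratios = []
        for seed in range(20):
            v1 = gen_density_field(ACFParams(d=2.5, sigma_n_sq=1e-3),
                                   shape, vox, seed).values.var()
            v3 = gen_density_field(ACFParams(d=2.5, sigma_n_sq=3e-3),
                                   shape, vox, seed).values.var()
            ratios.append(v3 / v1)
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.05)

    def test_empirical_acf_slope_matches_target(self):
        p = ACFParams(d=2.5)
        slopes = []
        for seed in range(20):
            f = gen_density_field(p, (72, 72, 72), 10.0, seed)
            r, b = empirical_acf_radial(f)
            sel = (r >= 2 * p.r_min) & (r <= p.r_max / 2) & (b > 0)
            coef = np.polyfit(np.log(r[sel]), np.log(b[sel]), 1)[0]
            slopes.append(coef)
        assert np.mean(slopes) == pytest.approx(p.d - 3.0, abs=0.1)

    def test_coarse_axial_voxel_rejected(self):
        with pytest.raises(ValueError):
            gen_density_field(ACFParams(d=2.5), (16, 16, 60),
                              (458, 458, 20.0), seed=0)

    def test_short_axial_extent_rejected(self):
        with pytest.raises(ValueError):
            gen_density_field(ACFParams(d=2.5), (16, 16, 32),
                              (458, 458, 10.0), seed=0)


class TestSpectralCube:
    def test_zero_density_gives_zero_spectra(self, optics):
        field = DensityField(np.zeros((8, 8, 300)), (458.0, 458.0, 10.0), 0)
        cube = simulate_spectral_cube(field, optics, noise_sd=0.0)
        assert np.all(cube.data == 0.0)

    def test_spectra_linear_in_alpha(self, optics, cube_factory):
        p = ACFParams(d=2.5)
        field = gen_density_field(p, (8, 8, 300), (458, 458, 10), seed=3)
        c1 = simulate_spectral_cube(field, optics, noise_sd=0.0)
        c2 = simulate_spectral_cube(
            field, optics.replace(alpha=2 * optics.alpha), noise_sd=0.0)
        np.testing.assert_allclose(c2.data, 2.0 * c1.data, rtol=1e-12)

    def test_seed_determinism_with_noise(self, optics):
        p = ACFParams(d=2.5)
        field = gen_density_field(p, (8, 8, 300), (458, 458, 10), seed=3)
        a = simulate_spectral_cube(field, optics, noise_sd=1e-4, seed=9)
        b = simulate_spectral_cube(field, optics, noise_sd=1e-4, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_mean_sigma_matches_forward_model(self, optics, cube_factory):
        """Keystone consistency: simulator Sigma converges to the forward
        model prediction."""
        cube = cube_factory(2.6, nxy=64, seed=21)
        emp = cube.data.std(axis=2, ddof=0).mean()
        pred = forward_sigma(ACFParams(d=2.6), optics)
        assert emp == pytest.approx(pred, rel=0.10)


class TestNucleusMasks:
    def test_zero_nuclei(self):
        labels, ellipses = gen_nucleus_masks(0, (64, 64), seed=0)
        assert labels.max() == 0 and ellipses == []

    def test_five_distinct_labels(self):
        labels, ellipses = gen_nucleus_masks(5, (128, 128), seed=1)
        assert sorted(np.unique(labels)) == [0, 1, 2, 3, 4, 5]
        assert len(ellipses) == 5

    def test_area_matches_analytic_ellipse(self):
        labels, ellipses = gen_nucleus_masks(4, (256, 256),
                                             radius_range=(12, 20), seed=2)
        for e in ellipses:
            pixels = int((labels == e.label).sum())
            analytic = np.pi * e.a * e.b
            assert pixels == pytest.approx(analytic, rel=0.05)

    def test_impossible_placement_raises(self):
        with pytest.raises(PlacementError):
            gen_nucleus_masks(40, (48, 48), radius_range=(10, 12), seed=0,
                              max_attempts=50)

    def test_seed_determinism(self):
        a, _ = gen_nucleus_masks(3, (96, 96), seed=5)
        b, _ = gen_nucleus_masks(3, (96, 96), seed=5)
        np.testing.assert_array_equal(a, b)


class TestCohort:
    def test_degenerate_sds_give_group_mean(self):
        spec = CohortSpec(
            groups=[GroupSpec("g", 3, 2.4, sd_between=0.0, sd_within=0.0)],
            cells_per_patient=31, seed=0)
        coh = gen_cohort(spec)
        for p in coh.patients:
            np.testing.assert_allclose(p.cell_d_values, 2.4)

    def test_group_sizes_match_spec(self):
        spec = two_group_spec(0.8, n_per_group=7, seed=1)
        coh = gen_cohort(spec)
        tab = coh.to_patient_table()
        assert (tab["group"].value_counts() == 7).all()

    def test_seed_determinism(self):
        spec = two_group_spec(0.8, n_per_group=5, seed=3)
        a, b = gen_cohort(spec), gen_cohort(spec)
        for pa, pb in zip(a.patients, b.patients):
            np.testing.assert_array_equal(pa.cell_d_values, pb.cell_d_values)
            assert pa.age == pb.age and pa.sex == pb.sex

    def test_cells_floor_enforced(self):
        with pytest.raises(ValueError):
            CohortSpec(groups=[GroupSpec("g", 2, 2.4)], cells_per_patient=30)

    def test_unique_patient_ids_required(self):
        spec = two_group_spec(0.5, n_per_group=3, seed=0)
        coh = gen_cohort(spec)
        coh.patients[1].patient_id = coh.patients[0].patient_id
        with pytest.raises(ValueError):
            Cohort(coh.patients)

    def test_stratified_shift_reproduces_effect_size(self):
        """Mean sample Cohen's d on patient means tracks the nominal shift."""
        ds = []
        for seed in range(15):
            coh = gen_cohort(two_group_spec(0.83, n_per_group=50, seed=seed))
            tab = coh.to_patient_table()
            means = coh.to_cell_table().groupby("patient_id")["d"].mean()
            a = means[tab.loc[tab.label == "control", "patient_id"]].to_numpy()
            b = means[tab.loc[tab.label == "case", "patient_id"]].to_numpy()
            sp = np.sqrt(((len(a) - 1) * a.var(ddof=1)
                          + (len(b) - 1) * b.var(ddof=1))
                         / (len(a) + len(b) - 2))
            ds.append((b.mean() - a.mean()) / sp)
        assert np.mean(ds) == pytest.approx(0.83, abs=0.1)


class TestHistoryTable:
    def test_strata_counts_and_rates(self):
        spec = five_group_risk_spec(n_per_group=6, seed=2)
        coh = gen_cohort(spec)
        table = rk.default_risk_table()
        hist = gen_history_table(coh, table)
        assert len(hist) == len(coh.patients)
        for _, row in hist.head(10).iterrows():
            expected = table.rates[(row.history, row.sex, row.age_stratum)]
            assert row.annual_aa_incidence == expected.annual_aa_incidence

    def test_no_cancer_history_gives_empty_nc_pool(self):
        spec = CohortSpec(
            groups=[GroupSpec("g", 4, 2.4, history="no_history")],
            cells_per_patient=31, seed=0)
        hist = gen_history_table(gen_cohort(spec), rk.default_risk_table())
        assert (hist["pool"] == "na").all()

    def test_unknown_history_category_raises(self):
        spec = CohortSpec(
            groups=[GroupSpec("g", 2, 2.4, history="mystery")],
            cells_per_patient=31, seed=0)
        with pytest.raises(KeyError):
            gen_history_table(gen_cohort(spec), rk.default_risk_table())


class TestNucleusImage:
    def test_seed_determinism(self):
        a = gen_nucleus_image(2.5, seed=4)
        b = gen_nucleus_image(2.5, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_texture_coarsens_with_d(self):
        """Higher packing scaling produces longer-range texture (smaller
        mean gradient inside the nucleus)."""
        grads = []
        for d in (2.3, 2.8):
            g = []
            for seed in range(10):
                img = gen_nucleus_image(d, seed=seed)
                gy, gx = np.gradient(np.nan_to_num(img, nan=d))
                g.append(np.hypot(gy, gx)[np.isfinite(img)].mean())
            grads.append(np.mean(g))
        assert grads[1] < grads[0]
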