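"""Generator behaviour: coverage mixture, spectra, images, cohorts."""

import numpy as np
import pandas as pd
import pytest

from fruitlet import synthesis as syn
from fruitlet import trichomes as tr
from fruitlet.spectra import Band, Spectrum, band_mean, compute_cci, compute_pwi, make_grid

RED = Band(640, 700)


class TestCoverageFraction:
    def test_saturation_point(self):
        assert syn.coverage_fraction(5.0, 5.0) == 1.0

    def test_clamped_above_saturation(self):
        assert syn.coverage_fraction(40.0, 5.0) == 1.0

    def test_two_thirds_power(self):
        assert syn.coverage_fraction(5.0 / 8.0, 5.0) == pytest.approx(0.25)

    def test_zero_weight(self):
        assert syn.coverage_fraction(0.0, 5.0) == 0.0


class TestTissueReflectance:
    def test_absorbers_off_returns_template(self):
        # With both absorbers off the template's control points come back.
        wl = np.array([303.0, 375.0, 425.0, 560.0, 750.0, 900.0, 1098.0])
        refl = syn.tissue_reflectance(wl, 0.0, 0.0, 0.0)
        assert refl == pytest.approx([0.12, 0.15, 0.55, 0.45, 0.85, 0.85, 0.80])

    def test_water_absorber_deepens_dip(self):
        wl = make_grid()
        base = syn.tissue_reflectance(wl, 0.0, 0.0)
        wet = syn.tissue_reflectance(wl, 0.0, 0.5)
        i960, i895 = np.argmin(np.abs(wl - 960)), np.argmin(np.abs(wl - 895))
        assert wet[i960] / wet[i895] < base[i960] / base[i895]

    def test_red_band_monotone_in_chlorophyll(self):
        wl = make_grid()
        means = [
            np.mean(syn.tissue_reflectance(wl, c, 0.0)[(wl >= 640) & (wl <= 700)])
            for c in (0.0, 0.3, 0.6, 1.0)
        ]
        assert np.all(np.diff(means) < 0)

    def test_reflectance_minimum_in_green_orange_trough(self):
        # Moderate chlorophyll levels put the visible minimum in 560-640 nm.
        wl = make_grid()
        visible = (wl >= 450) & (wl <= 720)
        refl = syn.tissue_reflectance(wl, 0.7, 0.0)
        assert 560 <= wl[visible][np.argmin(refl[visible])] <= 640


class TestMeasuredSpectrum:
    def test_zero_weight_collapses_to_background(self):
        p = syn.fuji_params()
        s = syn.measured_spectrum(0.0, 1000.0, 30.0, p, noise=False)
        assert np.allclose(s.reflectance, syn.BACKGROUND_REFLECTANCE)
        assert compute_cci(s) == pytest.approx(1.0)
        assert compute_pwi(s) == pytest.approx(1.0)

    def test_cci_sweep_unimodal_with_peak_at_saturation(self):
        p = syn.fuji_params()
        weights = np.arange(0.5, 10.3, 0.25)
        cci = [
            compute_cci(
                syn.measured_spectrum(
                    w, p.chl_conc_intercept + p.chl_conc_slope * w, 20.0, p, noise=False
                )
            )
            for w in weights
        ]
        i = int(np.argmax(cci))
        assert abs(weights[i] - p.w_sat_g) <= 0.3
        diffs = np.sign(np.diff(cci))
        assert np.all(diffs[:i] > 0) and np.all(diffs[i:] < 0)
        # higher at saturation than at either extreme of the size range
        assert cci[i] > cci[0] and cci[i] > cci[-1]

    def test_pwi_minimum_at_saturation(self):
        p = syn.honeycrisp_params()
        at_sat = compute_pwi(syn.measured_spectrum(p.w_sat_g, 700.0, 20.0, p, noise=False))
        small = compute_pwi(syn.measured_spectrum(0.2, 840.0, 40.0, p, noise=False))
        assert at_sat < small

    def test_red_band_mixture_monotonicity(self):
        # Pre-saturation the 640-700 nm mean falls with weight (coverage +
        # chlorophyll); post-saturation it recovers (dilution + backscatter).
        p = syn.fuji_params()

        def red(w):
            s = syn.measured_spectrum(
                w, p.chl_conc_intercept + p.chl_conc_slope * w, 20.0, p, noise=False
            )
            return band_mean(s, RED)

        pre = [red(w) for w in np.linspace(0.3, p.w_sat_g, 12)]
        post = [red(w) for w in np.linspace(p.w_sat_g, 10.3, 12)]
        assert np.all(np.diff(pre) < 0)
        assert np.all(np.diff(post) > 0)

    def test_fixed_seed_reproducible(self):
        p = syn.fuji_params()
        a = syn.measured_spectrum(3.0, 900.0, 25.0, p, rng=np.random.default_rng(5))
        b = syn.measured_spectrum(3.0, 900.0, 25.0, p, rng=np.random.default_rng(5))
        assert np.array_equal(a.reflectance, b.reflectance)

    def test_trichome_removal_lowers_reflectance(self):
        p = syn.honeycrisp_params()
        intact = syn.measured_spectrum(0.5, 800.0, 40.0, p, noise=False)
        removed = syn.measured_spectrum(
            0.5, 800.0, 40.0, p, noise=False, trichome_state="removed"
        )
        assert np.all(intact.reflectance >= removed.reflectance)


class TestAbsorbanceGeneration:
    def test_system_determinant_well_conditioned(self):
        det = float(np.linalg.det(syn._CHL_MATRIX))
        assert det == pytest.approx(13.36 * 27.43 - 5.19**2)
        assert det == pytest.approx(339.5287)

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError):
            syn.absorbance_from_chlorophyll(100.0, 40.0, noise_sd=0.01)


class TestTrichomeImage:
    def test_zero_target_blank(self, rng):
        img = syn.generate_trichome_image(0.0, rng=rng)
        assert not img.truth_mask.any()
        assert tr.quantify(img).as_tuple() == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("target", [5.0, 20.0, 50.0])
    def test_realized_truth_within_half_point(self, target, rng):
        img = syn.generate_trichome_image(
            target, shape=(240, 180), mm_per_pixel=0.05, rng=rng
        )
        realized = 100.0 * img.truth_mask.mean()
        assert realized == pytest.approx(target, abs=0.5)

    def test_fixed_seed_reproducible(self):
        a = syn.generate_trichome_image(15.0, rng=np.random.default_rng(3))
        b = syn.generate_trichome_image(15.0, rng=np.random.default_rng(3))
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.truth_mask, b.truth_mask)

    def test_unreachable_target_rejected(self, rng):
        with pytest.raises(ValueError, match="95"):
            syn.generate_trichome_image(99.0, rng=rng)


class TestCohorts:
    def test_sizes_and_ranges(self, default_cohorts):
        expected = [("Fuji", 23, 47), ("Fuji", 36, 45),
                    ("Honeycrisp", 20, 36), ("Honeycrisp", 29, 29)]
        for cohort, (cultivar, dafb, n) in zip(default_cohorts, expected):
            rec = cohort.records
            assert len(rec) == n
            assert (rec["cultivar"] == cultivar).all()
            lo, hi = cohort.config.weight_range_g
            assert rec["fresh_g"].between(lo, hi).all()
            assert (rec["dry_g"] < rec["fresh_g"]).all()
            for col in ("trichome_calyx_pct", "trichome_centre_pct", "trichome_pedicel_pct"):
                assert rec[col].between(0, 100).all()

    def test_same_seed_identical_tables(self):
        cfg = syn.default_cohort_configs(9)[0]
        a = syn.generate_cohort(cfg)
        b = syn.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.records, b.records, check_exact=True)
        pd.testing.assert_frame_equal(a.absorbance, b.absorbance, check_exact=True)

    def test_noise_free_identifiability(self, noise_free_cohorts):
        # With noise disabled every downstream quantification recovers the
        # generator truth to numerical precision.
        from fruitlet.io import quantify_chlorophyll_table, quantify_spectra_table

        cohort = noise_free_cohorts[0]
        chl = quantify_chlorophyll_table(cohort.absorbance)
        assert np.allclose(chl["chl_total"], cohort.records["chl_conc"], atol=1e-9)
        assert np.allclose(chl["chl_a"], cohort.records["chl_a"], atol=1e-9)
        idx = quantify_spectra_table(cohort.spectra)
        assert np.allclose(idx["cci"], cohort.records["cci"], atol=1e-12)
        assert np.allclose(idx["pwi"], cohort.records["pwi"], atol=1e-12)

    def test_noise_free_expected_water_content(self):
        # The solved dry intercept makes the weight-averaged water content
        # equal the 85 % target over the cultivar's sampled weight mixture.
        for params in (syn.fuji_params(), syn.honeycrisp_params()):
            configs = [c for c in syn.default_cohort_configs()
                       if c.cultivar == params.name]
            a = syn.solve_dry_intercept(params, configs)
            total, weight = 0.0, 0
            for cfg in configs:
                w = np.linspace(*cfg.weight_range_g, 20001)
                water = 100.0 * (1 - (a + params.dry_slope * w) / w)
                total += cfg.n * water.mean()
                weight += cfg.n
            assert total / weight == pytest.approx(85.0, abs=0.05)

    def test_trichome_lines_cross_at_reported_weights(self):
        # Calyx and pedicel trends intersect near 6.5 g (Fuji) / 2.5 g (HC).
        for params, crossing in ((syn.fuji_params(), 6.5), (syn.honeycrisp_params(), 2.5)):
            c, p = params.trichome_calyx, params.trichome_pedicel
            x = (p.intercept_pct - c.intercept_pct) / (c.slope_pct_per_g - p.slope_pct_per_g)
            assert x == pytest.approx(crossing, abs=0.1)
            assert c(0.2) > params.trichome_centre(0.2)
            assert c(0.2) > p(0.2)

    def test_default_pca_subset_has_155_spectra(self, default_cohorts):
        assert len(syn.default_pca_spectra(default_cohorts)) == 155

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            syn.CohortConfig("Fuji", 23, 0, (0.2, 1.6))
        with pytest.raises(ValueError):
            syn.CohortConfig("Fuji", 23, 10, (1.6, 0.2))
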