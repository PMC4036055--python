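"""Fick's-law flux estimation, oxic-zone geometry, and zone-rate inversion."""

import numpy as np
import pytest

import rhizoflux as rf
from rhizoflux.exceptions import ProfileValidationError, UnsupportedAnalyteError


class TestEstimateFlux:
    @pytest.mark.parametrize("window", [2, 3, 5, 10])
    def test_exact_on_linear_profile(self, linear_o2, window):
        """J = phi D |dC/dz| 3600 = 2.06e-5 * 1.0 * 3600 for a unit gradient."""
        est = rf.estimate_flux(linear_o2, 0, window=window)
        assert est.flux == pytest.approx(2.06e-5 * 1.0 * 3600, rel=1e-12)
        assert est.slope == pytest.approx(-1.0, rel=1e-12)
        assert est.slope_se == pytest.approx(0.0, abs=1e-9)

    def test_flat_profile_zero_flux(self):
        prof = rf.MicroProfile(rf.Analyte.O2, np.linspace(0, 0.1, 11), np.full(11, 0.05))
        est = rf.estimate_flux(prof, 0, window=4)
        assert est.flux == 0.0
        assert est.slope_se == pytest.approx(0.0, abs=1e-15)

    def test_porosity_scales_linearly(self, linear_o2):
        full = rf.estimate_flux(linear_o2, 0, porosity=1.0)
        half = rf.estimate_flux(linear_o2, 0, porosity=0.5)
        assert half.flux == pytest.approx(full.flux / 2, rel=1e-12)

    def test_backward_window_at_profile_end(self, linear_o2):
        est = rf.estimate_flux(linear_o2, linear_o2.n - 1, window=3)
        assert est.flux == pytest.approx(2.06e-5 * 3600, rel=1e-12)

    def test_ph_rejected(self):
        prof = rf.MicroProfile(rf.Analyte.PH, [0, 0.005, 0.01], [7.0, 7.1, 7.2])
        with pytest.raises(UnsupportedAnalyteError):
            rf.estimate_flux(prof, 0)

    def test_window_too_small_rejected(self, linear_o2):
        with pytest.raises(ProfileValidationError):
            rf.estimate_flux(linear_o2, 0, window=1)


class TestEstimateROL:
    def _radial(self, conc):
        z = np.linspace(0, 0.05, len(conc))
        return rf.MicroProfile(rf.Analyte.O2, z, conc,
                               geometry=rf.Geometry.RADIAL_FROM_ROOT,
                               apex_distance_mm=25.0)

    def test_linear_shell_gradient(self):
        """0.08 -> 0 umol/cm3 over 0.5 mm gives ROL = D*(0.08/0.05)*3600."""
        est = rf.estimate_rol(self._radial(np.linspace(0.08, 0.0, 11)))
        assert est.rol == pytest.approx(2.06e-5 * (0.08 / 0.05) * 3600, rel=1e-12)
        assert not est.inward_flux
        assert est.apex_distance_mm == 25.0

    def test_flat_profile_zero_rol(self):
        est = rf.estimate_rol(self._radial(np.full(11, 0.04)))
        assert est.rol == 0.0

    def test_increasing_outward_flagged_negative(self):
        est = rf.estimate_rol(self._radial(np.linspace(0.0, 0.08, 11)))
        assert est.rol < 0
        assert est.inward_flux

    def test_too_few_points_rejected(self):
        prof = self._radial(np.linspace(0.08, 0.0, 3))
        with pytest.raises(ProfileValidationError):
            rf.estimate_rol(prof, window=3)

    def test_vertical_geometry_rejected(self, linear_o2):
        with pytest.raises(ProfileValidationError):
            rf.estimate_rol(linear_o2)


class TestOxicMetrics:
    def test_fig5_penetration_and_shell(self, fig5_clean):
        """Recovers the constructed geometry: anoxia 1.1 mm below the surface,
        a 0.5 mm oxic shell against the root, each within one 50 um step."""
        m = rf.oxic_metrics(fig5_clean, threshold=1e-3)
        assert m.penetration_depth_cm == pytest.approx(0.11, abs=0.005)
        assert m.shell_thickness_cm == pytest.approx(0.05, abs=0.005)
        assert not m.not_reached and not m.never_oxic

    def test_everywhere_oxic_flagged_not_reached(self):
        z = np.linspace(0, 0.1, 11)
        prof = rf.MicroProfile(rf.Analyte.O2, z, 0.1 - 0.5 * z)
        m = rf.oxic_metrics(prof)
        assert m.penetration_depth_cm == pytest.approx(0.1)
        assert m.not_reached

    def test_never_oxic_zero_metrics(self):
        z = np.linspace(0, 0.1, 11)
        prof = rf.MicroProfile(rf.Analyte.O2, z, np.full(11, 1e-4))
        m = rf.oxic_metrics(prof)
        assert m.never_oxic
        assert m.penetration_depth_cm == 0.0
        assert m.shell_thickness_cm == 0.0

    def test_radial_shell_measured_from_root_side(self):
        z = np.linspace(0, 0.1, 21)
        conc = np.where(z <= 0.05, 0.08 * (1 - z / 0.05), 0.0)
        prof = rf.MicroProfile(rf.Analyte.O2, z, conc,
                               geometry=rf.Geometry.RADIAL_FROM_ROOT)
        m = rf.oxic_metrics(prof, threshold=1e-3)
        assert m.shell_thickness_cm == pytest.approx(0.05, abs=0.005)

    def test_nonpositive_threshold_rejected(self, fig5_clean):
        with pytest.raises(ProfileValidationError):
            rf.oxic_metrics(fig5_clean, threshold=0.0)


class TestZoneRateModel:
    def test_noise_free_single_zone_recovery(self):
        """The generating rate is recovered to 1e-4 relative with k = 1."""
        spec = rf.scenario_spec("uniform_consumption")
        clean = rf.solve_steady_state(spec)
        res = rf.ZoneRateModel(clean).fit(k_max=3)
        assert res.k == 1
        assert res.rates[0] == pytest.approx(spec.zones.rates[0], rel=1e-4)

    def test_noise_free_two_zone_recovery(self, two_zone_clean):
        """Both rates to 1e-3 relative; the boundary lands on the true node."""
        truth = rf.scenario_spec("two_zone").zones
        res = rf.ZoneRateModel(two_zone_clean).fit(k_max=3)
        assert res.k == 2
        np.testing.assert_allclose(res.rates, truth.rates, rtol=1e-3)
        assert abs(res.zone_model.boundaries[1] - truth.boundaries[1]) <= 0.005 + 1e-12

    def test_flat_profile_zero_rates(self):
        prof = rf.MicroProfile(rf.Analyte.O2, np.linspace(0, 0.1, 21), np.full(21, 0.05))
        res = rf.ZoneRateModel(prof).fit(k_max=3)
        assert res.k == 1
        assert res.rates[0] == pytest.approx(0.0, abs=1e-9)

    def test_conservation_of_fitted_model(self, two_zone_clean):
        res = rf.ZoneRateModel(two_zone_clean).fit(k_max=3)
        j0, jl = res.boundary_fluxes()
        assert (j0 - jl) == pytest.approx(res.integrated_rate(), rel=1e-8)

    def test_fixed_boundaries_skip_selection(self, two_zone_clean):
        truth = rf.scenario_spec("two_zone").zones
        res = rf.ZoneRateModel(two_zone_clean).fit(boundaries=truth.boundaries)
        np.testing.assert_allclose(res.rates, truth.rates, rtol=1e-9)

    def test_off_grid_boundary_rejected(self, two_zone_clean):
        with pytest.raises(ProfileValidationError):
            rf.ZoneRateModel(two_zone_clean).fit(boundaries=[0.0, 0.1013, 0.2])

    def test_three_zone_layered_scenario(self, fig5_clean):
        """The layered consumption/gap/shell structure is recovered from the
        noise-free profile with boundaries on the true nodes."""
        truth = rf.scenario_spec("fig5_o2").zones
        res = rf.ZoneRateModel(fig5_clean).fit(k_max=4)
        assert res.k == 3
        np.testing.assert_allclose(res.zone_model.boundaries, truth.boundaries,
                                   atol=1e-12)
        np.testing.assert_allclose(res.rates, truth.rates, rtol=1e-6, atol=1e-9)

    def test_summary_reports_zones_and_fluxes(self, two_zone_clean):
        res = rf.ZoneRateModel(two_zone_clean).fit(k_max=3)
        text = res.summary()
        assert "zones selected: 2" in text
        assert "umol cm-2 h-1" in text

    def test_plot_returns_axes(self, two_zone_clean):
        import matplotlib
        matplotlib.use("Agg")
        res = rf.ZoneRateModel(two_zone_clean).fit(k_max=3)
        ax = res.plot()
        assert ax.get_xlabel() == "position (mm)"

    def test_from_dataframe_roundtrip(self, two_zone_clean):
        frame = two_zone_clean.to_frame()
        model = rf.ZoneRateModel.from_dataframe(frame, analyte=rf.Analyte.O2)
        res = model.fit(k_max=3)
        assert res.k == 2

    def test_ph_profile_rejected(self):
        prof = rf.MicroProfile(rf.Analyte.PH, np.linspace(0, 0.1, 21), np.full(21, 7.0))
        with pytest.raises(UnsupportedAnalyteError):
            rf.ZoneRateModel(prof)

    def test_too_few_points_for_kmax(self):
        prof = rf.MicroProfile(rf.Analyte.O2, np.linspace(0, 0.03, 7),
                               np.linspace(0.1, 0.05, 7))
        with pytest.raises(ProfileValidationError):
            rf.ZoneRateModel(prof).fit(k_max=5)


class TestIntegrateZoneRates:
    def test_unit_thickness_identity(self):
        zm = rf.ZoneModel([0.0, 1.0], [0.42])
        assert rf.integrate_zone_rates(zm) == pytest.approx(0.42)

    def test_equal_and_opposite_zones_cancel(self):
        zm = rf.ZoneModel([0.0, 0.5, 1.0], [0.3, -0.3])
        assert rf.integrate_zone_rates(zm) == pytest.approx(0.0, abs=1e-15)
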