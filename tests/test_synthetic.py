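"""Forward reaction-diffusion solver and the synthetic profile generator.

The solver is checked against closed-form solutions (linear, parabolic,
and the piecewise-parabolic two-zone solution derived independently by
matching value and slope at the rate jump), and for exact discrete flux
conservation.
"""

import numpy as np
import pytest

import rhizoflux as rf
from rhizoflux.exceptions import InfeasibleScenarioError, ProfileValidationError
from rhizoflux.synthetic import SECONDS_PER_HOUR


def _spec(length, spacing, zones, bc, d=2.06e-5, **kw):
    return rf.ScenarioSpec(
        length_cm=length, spacing_cm=spacing, d_cm2_s=d,
        zones=rf.ZoneModel(*zones), bc=bc, **kw,
    )


class TestClosedForms:
    def test_zero_rate_is_linear(self):
        spec = _spec(0.1, 0.005, ([0.0, 0.1], [0.0]),
                     rf.BoundaryConditions.dirichlet(0.1, 0.0))
        prof = rf.solve_steady_state(spec)
        np.testing.assert_allclose(prof.concentrations, 0.1 * (1 - prof.positions / 0.1),
                                   atol=1e-15)
        assert prof.concentrations[10] == pytest.approx(0.05, rel=1e-12)

    def test_constant_consumption_parabola(self):
        """C(z) = C0 - R/(phi D 3600) (L z - z^2/2) with zero flux at L."""
        L, R, D, C0 = 0.1, 0.3, 2.06e-5, 0.1
        spec = _spec(
            L, 0.001, ([0.0, L], [R]),
            rf.BoundaryConditions(
                rf.BoundaryCondition(rf.BCKind.FIXED_CONCENTRATION, C0),
                rf.BoundaryCondition(rf.BCKind.FIXED_FLUX, 0.0),
            ),
            d=D,
        )
        prof = rf.solve_steady_state(spec)
        z = prof.positions
        closed = C0 - (R / (D * SECONDS_PER_HOUR)) * (L * z - z**2 / 2)
        err = np.max(np.abs(prof.concentrations - closed) / np.abs(closed).max())
        assert err < 1e-6

    def test_second_order_convergence_with_rate_jumps(self):
        """Against the exact piecewise-parabolic solution, halving the grid
        step divides the max error by ~4 (2nd-order scheme).

        The rate jump is placed off the node grid: with the jump on a
        node the finite-volume scheme is nodally exact and leaves no
        truncation error to measure.
        """
        D, L, c0, cL = 2.06e-5, 0.2, 0.1, 0.09
        mid = 0.1 + 0.005 / 3.0
        a1 = 0.4 / SECONDS_PER_HOUR / D   # curvature C'' in each zone
        a2 = -0.2 / SECONDS_PER_HOUR / D
        # C1 = A + B z + a1 z^2/2 on [0, mid]; C2 = E + F z + a2 z^2/2 on
        # [mid, L]; unknowns from the two Dirichlet values plus C0/C1
        # continuity of value and slope at the interface
        M = np.array([
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, L],
            [1.0, mid, -1.0, -mid],
            [0.0, 1.0, 0.0, -1.0],
        ])
        rhs = np.array([
            c0,
            cL - a2 * L**2 / 2,
            (a2 - a1) * mid**2 / 2,
            (a2 - a1) * mid,
        ])
        A, B, E, F = np.linalg.solve(M, rhs)

        def exact(z):
            return np.where(z <= mid, A + B * z + a1 * z**2 / 2,
                            E + F * z + a2 * z**2 / 2)

        errs = []
        for h in (0.005, 0.0025):
            spec = _spec(0.2, h, ([0.0, mid, 0.2], [0.4, -0.2]),
                         rf.BoundaryConditions.dirichlet(c0, cL), d=D)
            prof = rf.solve_steady_state(spec)
            errs.append(np.max(np.abs(prof.concentrations - exact(prof.positions))))
        assert errs[0] > 1e-8  # genuine truncation error present
        assert errs[0] / errs[1] > 3.0

        # with the jump on a grid node the scheme is nodally exact
        spec = _spec(0.2, 0.005, ([0.0, 0.1, 0.2], [0.4, -0.2]),
                     rf.BoundaryConditions.dirichlet(c0, cL), d=D)
        prof = rf.solve_steady_state(spec)
        M[2] = [1.0, 0.1, -1.0, -0.1]
        M[3] = [0.0, 1.0, 0.0, -1.0]
        rhs[2] = (a2 - a1) * 0.1**2 / 2
        rhs[3] = (a2 - a1) * 0.1
        A, B, E, F = np.linalg.solve(M, rhs)
        on_node = np.where(prof.positions <= 0.1,
                           A + B * prof.positions + a1 * prof.positions**2 / 2,
                           E + F * prof.positions + a2 * prof.positions**2 / 2)
        assert np.max(np.abs(prof.concentrations - on_node)) < 1e-12

    def test_cylindrical_laplace_log_solution(self):
        """Zero-rate radial diffusion around a root follows C ~ ln(r/r0)."""
        r0, L = 0.025, 0.05
        spec = _spec(L, 0.0005, ([0.0, L], [0.0]),
                     rf.BoundaryConditions.dirichlet(0.08, 0.0),
                     cylindrical=True, root_radius_cm=r0)
        prof = rf.solve_steady_state(spec)
        r = r0 + prof.positions
        closed = 0.08 * (np.log((r0 + L) / r) / np.log((r0 + L) / r0))
        assert np.max(np.abs(prof.concentrations - closed)) < 1e-5


class TestConservation:
    def test_boundary_flux_difference_equals_zone_integral(self, fig5_clean):
        """Discrete conservation: J(0) - J(L) == sum(R_i h_i) to 1e-8 relative."""
        spec = rf.scenario_spec("fig5_o2")
        res = rf.ZoneRateModel(fig5_clean).fit(boundaries=spec.zones.boundaries)
        j0, jl = res.boundary_fluxes()
        total = res.integrated_rate()
        assert (j0 - jl) == pytest.approx(total, rel=1e-8)

    def test_infeasible_rates_raise(self):
        spec = _spec(0.1, 0.005, ([0.0, 0.1], [50.0]),
                     rf.BoundaryConditions.dirichlet(0.01, 0.01))
        with pytest.raises(InfeasibleScenarioError):
            rf.solve_steady_state(spec)


class TestNoise:
    def test_zero_sigma_is_identity(self, fig5_clean):
        assert rf.add_noise(fig5_clean, 0.0) is fig5_clean

    def test_seeded_noise_is_deterministic(self, fig5_clean):
        a = rf.add_noise(fig5_clean, 1e-3, seed=7)
        b = rf.add_noise(fig5_clean, 1e-3, seed=7)
        np.testing.assert_array_equal(a.concentrations, b.concentrations)

    def test_missing_seed_rejected(self, fig5_clean):
        with pytest.raises(ProfileValidationError):
            rf.add_noise(fig5_clean, 1e-3)

    def test_noise_magnitude_matches_sigma(self):
        """Over 1e4 points the empirical noise SD is within 5% of sigma."""
        z = np.linspace(0, 1.0, 10_001)
        clean = rf.MicroProfile(rf.Analyte.O2, z, np.full_like(z, 0.5))
        noisy = rf.add_noise(clean, 1e-3, seed=3)
        sd = np.std(noisy.concentrations - clean.concentrations)
        assert sd == pytest.approx(1e-3, rel=0.05)

    def test_negative_values_truncated(self):
        z = np.linspace(0, 0.5, 5001)
        clean = rf.MicroProfile(rf.Analyte.O2, z, np.zeros_like(z))
        noisy = rf.add_noise(clean, 1e-3, seed=5)
        assert noisy.concentrations.min() == 0.0


class TestPresets:
    def test_fig5_o2_boundary_values(self, fig5_clean):
        assert fig5_clean.concentrations[0] == pytest.approx(0.055, rel=1e-9)
        assert fig5_clean.concentrations[-1] == pytest.approx(0.080, rel=1e-9)

    def test_fig5_o2_interior_anoxic_plateau(self, fig5_clean):
        """O2 vanishes (below 1 uM) between the surface oxic layer and the
        re-oxygenated shell near the root."""
        z = fig5_clean.positions
        c = fig5_clean.concentrations
        gap = (z > 0.115) & (z < 0.135)
        assert np.all(c[gap] < 1e-3)
        assert c[z == 0.0] > 1e-3 and c[-1] > 1e-3

    def test_uniform_preset_single_zone_truth(self):
        _, truth = rf.generate_rhizosphere_scenario("uniform_consumption", seed=1)
        assert truth.k == 1

    def test_same_preset_and_seed_identical(self):
        p1, z1 = rf.generate_rhizosphere_scenario("fig5_o2", seed=42)
        p2, z2 = rf.generate_rhizosphere_scenario("fig5_o2", seed=42)
        np.testing.assert_array_equal(p1.concentrations, p2.concentrations)
        np.testing.assert_array_equal(z1.rates, z2.rates)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ProfileValidationError):
            rf.generate_rhizosphere_scenario("fig7", seed=1)


class TestMonotonicity:
    def test_penetration_depth_decreases_with_consumption(self):
        """More uniform O2 consumption pushes the oxic front up."""
        depths = []
        for rate in (1.2, 1.3, 1.4):
            spec = _spec(
                0.1, 0.001, ([0.0, 0.1], [rate]),
                rf.BoundaryConditions(
                    rf.BoundaryCondition(rf.BCKind.FIXED_CONCENTRATION, 0.1),
                    rf.BoundaryCondition(rf.BCKind.FIXED_FLUX, 0.0),
                ),
            )
            prof = rf.solve_steady_state(spec)
            depths.append(rf.oxic_metrics(prof, threshold=0.02).penetration_depth_cm)
        assert depths[0] > depths[1] > depths[2]
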