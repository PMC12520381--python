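import numpy as np
import pytest

from taainv import gr_membrane as gm
from taainv.exceptions import ParameterError, SimulationError


class TestSensing:
    def test_homeostasis_gives_zero_deviation(self):
        assert gm.sensed_stress_deviation(100.0, 100.0, 0.0) == 0.0

    def test_overstress_formula(self):
        assert gm.sensed_stress_deviation(120.0, 100.0, 0.0) == \
            pytest.approx(0.2)

    def test_max_defect_formula(self):
        assert gm.sensed_stress_deviation(100.0, 100.0, 0.28) == \
            pytest.approx(-0.28)

    def test_target_stress(self):
        assert gm.equilibrium_target_stress(100.0, 0.0) == 100.0
        assert gm.equilibrium_target_stress(100.0, 0.5) == 200.0
        assert gm.equilibrium_target_stress(100.0, 0.28) == \
            pytest.approx(100.0 / 0.72)

    def test_total_sensing_loss_rejected(self):
        with pytest.raises(ParameterError):
            gm.equilibrium_target_stress(100.0, 1.0)
        with pytest.raises(ParameterError):
            gm.sensed_stress_deviation(100.0, 100.0, 1.0)


class TestConstituentLaws:
    def test_elastin_zero_at_natural_configuration(self, wall_params):
        lam = 1.0 / wall_params.G_e
        assert gm.elastin_stress(lam, wall_params) == pytest.approx(0.0)

    def test_elastin_monotone_increasing(self, wall_params):
        lams = np.linspace(0.5, 3.0, 50)
        s = gm.elastin_stress(lams, wall_params)
        assert np.all(np.diff(s) > 0)

    def test_elastin_derivative_matches_finite_difference(self, wall_params):
        h = 1e-7
        num = (gm.elastin_stress(1.0 + h, wall_params)
               - gm.elastin_stress(1.0 - h, wall_params)) / (2 * h)
        g2 = wall_params.G_e ** 2
        analytic = wall_params.c_e * (2 * g2 + 2 / g2)
        assert num == pytest.approx(analytic, rel=1e-6)

    def test_collagen_recovers_deposition_stress(self, wall_params):
        assert gm.collagen_elastic_stress(1.0, wall_params) == \
            pytest.approx(wall_params.s_h)

    def test_collagen_below_deposition_when_unloaded(self, wall_params):
        assert gm.collagen_elastic_stress(0.9, wall_params) < wall_params.s_h

    def test_collagen_derivative_analytic(self, wall_params):
        h = 1e-7
        num = (gm.collagen_elastic_stress(1.0 + h, wall_params)
               - gm.collagen_elastic_stress(1.0 - h, wall_params)) / (2 * h)
        analytic = wall_params.s_h * (2.0 + 2.0 * wall_params.k_c)
        assert num == pytest.approx(analytic, rel=1e-6)

    def test_damaged_elastin_below_intact(self, wall_params):
        lam = 1.5
        assert gm.damaged_elastin_stress(lam, 0.4, wall_params) < \
            gm.elastin_stress(lam, wall_params)


class TestEquilibriumSolve:
    def test_baseline_is_fixed_point(self, wall_params):
        lam, m_plus, h = gm.solve_equilibrated_node(0.0, 0.0, wall_params)
        assert lam == pytest.approx(1.0, abs=1e-6)
        assert h == pytest.approx(wall_params.h0, rel=1e-6)

    def test_elastin_damage_dilates(self, wall_params):
        lam, _, _ = gm.solve_equilibrated_node(0.3, 0.0, wall_params)
        assert lam > 1.0

    def test_mechanosensing_defect_dilates(self, wall_params):
        lam, _, _ = gm.solve_equilibrated_node(0.0, 0.2, wall_params)
        assert lam > 1.0

    def test_residual_vanishes_at_root(self, wall_params):
        rng = np.random.default_rng(0)
        tce = rng.uniform(0, 0.48, 64)
        tdl = rng.uniform(0, 0.28, 64)
        lam, _, _ = gm.solve_equilibrated_node(tce, tdl, wall_params)
        sigma_star = wall_params.sigma0 / (1.0 - tdl)
        resid = gm._equilibrium_residual(lam, tce, sigma_star, wall_params)
        assert np.abs(resid).max() < 1e-8 * wall_params.sigma0

    def test_solver_matches_brute_force_scan(self, wall_params):
        # independent oracle: argmin |R| over a fine stretch grid
        rng = np.random.default_rng(7)
        lam_grid = np.arange(*gm.LAM_BRACKET, 1e-3)
        for _ in range(100):
            tce = rng.uniform(0, 0.48)
            tdl = rng.uniform(0, 0.28)
            lam, _, _ = gm.solve_equilibrated_node(tce, tdl, wall_params)
            sigma_star = wall_params.sigma0 / (1.0 - tdl)
            resid = gm._equilibrium_residual(lam_grid, tce, sigma_star,
                                             wall_params)
            lam_scan = lam_grid[np.argmin(np.abs(resid))]
            assert abs(lam - lam_scan) <= 1e-3

    def test_invalid_insults_rejected(self, wall_params):
        with pytest.raises(ParameterError):
            gm.solve_equilibrated_node(-0.1, 0.0, wall_params)
        with pytest.raises(ParameterError):
            gm.solve_equilibrated_node(0.0, 1.0, wall_params)


class TestPressurize:
    def test_growth_pressure_recovers_grown_state(self, wall_params):
        lam, _, h = gm.solve_equilibrated_node(0.2, 0.1, wall_params)
        r, lam_el = gm.pressurize(lam, h, 0.2, wall_params.P_gr, wall_params)
        assert lam_el == pytest.approx(1.0, abs=1e-6)
        assert r == pytest.approx(lam * wall_params.r0, rel=1e-6)

    def test_radius_monotone_in_pressure(self, wall_params):
        lam, _, h = gm.solve_equilibrated_node(0.1, 0.05, wall_params)
        r_dia, _ = gm.pressurize(lam, h, 0.1, wall_params.P_dia, wall_params)
        r_sys, _ = gm.pressurize(lam, h, 0.1, wall_params.P_sys, wall_params)
        assert r_dia < r_sys

    def test_elastic_balance_residual_vanishes(self, wall_params):
        lam, _, h = gm.solve_equilibrated_node(0.25, 0.12, wall_params)
        _, lam_el = gm.pressurize(lam, h, 0.25, wall_params.P_dia,
                                  wall_params)
        resid = gm._pressurize_residual(lam_el, lam, h, 0.25,
                                        wall_params.P_dia, wall_params)
        assert abs(resid) < 1e-8 * wall_params.sigma0


class TestWallParams:
    def test_deposition_stress_must_exceed_set_point(self, wall_params):
        with pytest.raises(ParameterError):
            gm.WallParams(sigma0=wall_params.sigma0, m_e=wall_params.m_e,
                          c_e=wall_params.c_e, G_e=wall_params.G_e,
                          k_c=wall_params.k_c, s_h=0.5 * wall_params.sigma0)

    def test_homeostatic_identity_enforced(self, wall_params):
        with pytest.raises(ParameterError):
            gm.WallParams(sigma0=wall_params.sigma0, m_e=wall_params.m_e,
                          c_e=2 * wall_params.c_e, G_e=wall_params.G_e,
                          k_c=wall_params.k_c, s_h=wall_params.s_h)


class TestHomeostaticCalibration:
    def test_baseline_distensibility_on_target(self, wall_params):
        assert gm.baseline_distensibility(wall_params) == \
            pytest.approx(0.05442, abs=1e-5)

    def test_idempotent(self, wall_params):
        again = gm.homeostatic_calibration()
        assert again == wall_params

    def test_baseline_laplace_stress_equals_set_point(self, wall_params):
        # sigma_tt = P_gr * r0 / h0 must recover sigma0 at lam = 1
        sigma = wall_params.P_gr * wall_params.r0 / wall_params.h0
        assert sigma == pytest.approx(wall_params.sigma0, rel=1e-10)

    def test_unreachable_target_rejected(self):
        from taainv.exceptions import CalibrationError
        with pytest.raises(CalibrationError):
            gm.homeostatic_calibration(0.001)
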