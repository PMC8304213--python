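"""Two-compartment disposition: derived constants, integrator, AUC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pkpdcombo as pc

DRUGS = ["gemcitabine", "fluorouracil", "itraconazole"]


def positive_params():
    pos = st.floats(min_value=1e-3, max_value=1e5, allow_nan=False,
                    allow_infinity=False)
    rates = st.floats(min_value=1e-4, max_value=1.0, allow_nan=False,
                      allow_infinity=False)
    return st.builds(pc.PKParameters, vd1=pos, vd2=pos, cl=pos, k12=rates, k21=rates)


class TestDerivePK:
    @pytest.mark.parametrize("drug", DRUGS)
    def test_k10_and_vss_match_reported_tables(self, fx, drug):
        derived = pc.derive_pk(fx[drug])
        reported = fx["tables"]["pk"][drug]["reported"]
        assert derived.k10 == pytest.approx(reported["k10"], abs=5e-5)
        # printed Vss values carry a one-cent rounding inconsistency
        assert derived.vss == pytest.approx(reported["vss"], abs=0.02)

    @given(positive_params())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_lambda_roots_reconstruct_inputs(self, params):
        d = pc.derive_pk(params)
        s = params.k10 + params.k12 + params.k21
        assert d.lambda1 >= d.lambda2 > 0
        assert d.lambda1 + d.lambda2 == pytest.approx(s, rel=1e-10)
        assert d.lambda1 * d.lambda2 == pytest.approx(params.k10 * params.k21,
                                                      rel=1e-10)

    def test_vanishing_elimination_gives_vanishing_terminal_rate(self):
        params = pc.PKParameters(vd1=1000.0, vd2=1000.0, cl=1e-9, k12=0.1, k21=0.1)
        d = pc.derive_pk(params)
        assert d.lambda2 < 1e-11  # conserved system in the CL -> 0 limit

    @pytest.mark.parametrize("field", ["vd1", "vd2", "cl", "k12", "k21"])
    def test_non_positive_parameters_rejected(self, field):
        kwargs = dict(vd1=1.0, vd2=1.0, cl=1.0, k12=0.1, k21=0.1)
        kwargs[field] = 0.0
        with pytest.raises(ValueError):
            pc.PKParameters(**kwargs)


class TestRHS:
    def test_empty_system_passes_input_through(self, gem):
        assert pc.disposition_rhs(0.0, 0.0, gem, input_rate=3.5) == (3.5, 0.0, 0.0)

    def test_flows_from_loaded_central_compartment(self, gem):
        d_plasma, d_tissue, d_elim = pc.disposition_rhs(100.0, 0.0, gem)
        assert d_tissue == pytest.approx(0.0664, abs=1e-10)
        assert d_elim == pytest.approx(5.544283, abs=1e-4)
        assert d_plasma + d_tissue + d_elim == 0.0

    def test_return_flow_only(self, gem):
        d_plasma, d_tissue, d_elim = pc.disposition_rhs(0.0, 10.0, gem)
        assert d_plasma == 10.0 * gem.k21
        assert d_tissue == -10.0 * gem.k21
        assert d_elim == 0.0

    def test_negative_amounts_rejected(self, gem):
        with pytest.raises(ValueError):
            pc.disposition_rhs(-1.0, 0.0, gem)


class TestRegimenAndGrid:
    def test_infusion_fills_missing_quantity(self):
        reg = pc.DoseRegimen.infusion(rate=15.7, duration=120.0)
        assert reg.dose == pytest.approx(1884.0)
        reg2 = pc.DoseRegimen.infusion(dose=100.0, duration=60.0)
        assert reg2.rate == pytest.approx(100.0 / 60.0)

    def test_inconsistent_infusion_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            pc.DoseRegimen.infusion(dose=100.0, rate=2.0, duration=60.0)

    def test_repeat_interval_shorter_than_infusion_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            pc.DoseRegimen.infusion(dose=100.0, duration=60.0, n_doses=2,
                                    interval=30.0)

    def test_bolus_takes_no_rate(self):
        with pytest.raises(ValueError):
            pc.DoseRegimen("bolus", dose=900.0, rate=1.0)

    def test_grid_requires_commensurate_t_end(self):
        with pytest.raises(ValueError, match="integer multiple"):
            pc.SimulationGrid(t_end=100.01, h=0.02)
        with pytest.raises(ValueError):
            pc.SimulationGrid(t_end=100.0, h=0.02, method="rk5")


class TestIntegrator:
    def test_rk4_matches_analytic_solution(self, gem, gem_regimen, gem_trajectory):
        cf = pc.closed_form_concentration(gem, gem_regimen, gem_trajectory.times)
        mask = cf > 1e-12 * cf.max()
        rel = np.abs(gem_trajectory.plasma_conc[mask] - cf[mask]) / cf[mask]
        assert rel.max() < 1e-6

    def test_rk4_matches_analytic_solution_bolus(self, fu, fu_regimen, fu_trajectory):
        cf = pc.closed_form_concentration(fu, fu_regimen, fu_trajectory.times)
        mask = cf > 1e-12 * cf.max()
        rel = np.abs(fu_trajectory.plasma_conc[mask] - cf[mask]) / cf[mask]
        assert rel.max() < 1e-6

    def test_euler_error_within_first_order_budget(self, gem, gem_regimen):
        grid = pc.SimulationGrid(400.0, 0.02, method="euler")
        traj = pc.integrate_disposition(gem, gem_regimen, grid)
        cf = pc.closed_form_concentration(gem, gem_regimen, traj.times)
        assert np.abs(traj.plasma_conc - cf).max() / cf.max() < 1e-3

    @pytest.mark.parametrize("method", ["rk4", "euler"])
    def test_mass_balance(self, gem, gem_regimen, method):
        grid = pc.SimulationGrid(400.0, 0.02, method=method)
        traj = pc.integrate_disposition(gem, gem_regimen, grid)
        assert traj.mass_balance_error() < 1e-6

    def test_mass_balance_repeated_doses(self, itz):
        regimen = pc.DoseRegimen.infusion(dose=100.0, duration=60.0, n_doses=3,
                                          interval=1440.0)
        traj = pc.integrate_disposition(itz, regimen,
                                        pc.SimulationGrid(4000.0, 0.5))
        assert traj.mass_balance_error() < 1e-6

    def test_monotone_elimination_and_auc(self, gem_trajectory):
        assert np.all(np.diff(gem_trajectory.eliminated_amount) >= 0)
        assert np.all(np.diff(gem_trajectory.auc_plasma) >= 0)

    def test_concentration_amount_consistency(self, gem, gem_trajectory):
        np.testing.assert_allclose(
            gem_trajectory.plasma_conc,
            gem_trajectory.plasma_amount / gem.vd1 * 1000.0, rtol=1e-12)
        np.testing.assert_allclose(
            gem_trajectory.tissue_conc,
            gem_trajectory.tissue_amount / gem.vd2 * 1000.0, rtol=1e-12)

    def test_zero_dose_stays_zero(self, gem):
        regimen = pc.DoseRegimen.infusion(dose=0.0, duration=60.0)
        traj = pc.integrate_disposition(gem, regimen, pc.SimulationGrid(100.0, 0.1))
        assert traj.plasma_amount.max() == 0.0
        assert traj.auc_plasma[-1] == 0.0

    def test_infusion_cmax_at_end_of_infusion(self, gem_trajectory):
        assert gem_trajectory.t_cmax == pytest.approx(120.0, abs=0.02)
        assert gem_trajectory.cmax == pytest.approx(4.16, rel=0.01)

    def test_bolus_peak_is_initial_dilution(self, fu, fu_trajectory):
        assert fu_trajectory.plasma_conc[0] == pytest.approx(900.0 / fu.vd1 * 1000.0,
                                                             rel=1e-12)
        assert fu_trajectory.cmax == pytest.approx(97.14, rel=1e-3)

    @given(st.floats(min_value=0.5, max_value=50.0),
           st.floats(min_value=5.0, max_value=60.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_bolus_oracle_equivalence_random_params(self, dose, t_end):
        params = pc.PKParameters(vd1=500.0, vd2=800.0, cl=20.0, k12=0.05, k21=0.08)
        regimen = pc.DoseRegimen.bolus(dose)
        grid = pc.SimulationGrid(round(t_end / 0.05) * 0.05, 0.05)
        traj = pc.integrate_disposition(params, regimen, grid)
        cf = pc.closed_form_concentration(params, regimen, traj.times)
        assert np.abs(traj.plasma_conc - cf).max() <= 1e-8 * cf.max()
        assert traj.mass_balance_error() < 1e-9


class TestClosedForm:
    def test_bolus_at_time_zero_is_dose_over_vd1(self, fu):
        c0 = pc.closed_form_concentration(fu, pc.DoseRegimen.bolus(900.0), 0.0)
        assert c0 == pytest.approx(900.0 / fu.vd1 * 1000.0, rel=1e-12)

    def test_end_of_infusion_concentration(self, itz, itz_regimen):
        c60 = pc.closed_form_concentration(itz, itz_regimen, 60.0)
        assert c60 == pytest.approx(3.88, rel=0.01)

    def test_one_compartment_limit_is_monoexponential(self):
        params = pc.PKParameters(vd1=1000.0, vd2=1000.0, cl=50.0, k12=1e-12,
                                 k21=0.1)
        t = np.linspace(0.0, 60.0, 50)
        conc = pc.closed_form_concentration(params, pc.DoseRegimen.bolus(10.0), t)
        mono = 10.0 / 1000.0 * 1000.0 * np.exp(-params.k10 * t)
        np.testing.assert_allclose(conc, mono, rtol=1e-8)

    def test_repeated_root_degenerate_form_matches_integrator(self):
        # k12 ~ 0 with k10 == k21 collapses the two hybrid rates
        params = pc.PKParameters(vd1=1000.0, vd2=1000.0, cl=100.0, k12=1e-30,
                                 k21=0.1)
        regimen = pc.DoseRegimen.infusion(dose=50.0, duration=10.0)
        grid = pc.SimulationGrid(40.0, 0.01)
        traj = pc.integrate_disposition(params, regimen, grid)
        cf = pc.closed_form_concentration(params, regimen, traj.times)
        assert np.abs(traj.plasma_conc - cf).max() <= 1e-8 * cf.max()

    def test_repeated_regimens_unsupported(self, itz):
        regimen = pc.DoseRegimen.infusion(dose=100.0, duration=60.0, n_doses=2,
                                          interval=1440.0)
        with pytest.raises(ValueError, match="single-dose"):
            pc.closed_form_concentration(itz, regimen, 10.0)


class TestAUC:
    def test_rectangle_accumulator_constant_signal(self):
        values = np.full(501, 2.0)  # 2 ug/mL over 10 min at h=0.02
        auc = pc.cumulative_auc(values, 0.02)
        assert auc[-1] == pytest.approx(20.0, rel=1e-12)
        assert auc[0] == 0.0

    def test_zero_signal(self):
        assert pc.cumulative_auc(np.zeros(100), 0.5)[-1] == 0.0

    def test_trapezoid_variant_matches_reference_rule(self):
        values = np.sin(np.linspace(0, 3, 200)) + 1.5
        auc = pc.cumulative_auc(values, 0.1, rule="trapezoid")
        assert auc[-1] == pytest.approx(np.trapezoid(values, dx=0.1), rel=1e-12)

    @pytest.mark.parametrize("drug,regimen_name,expected", [
        ("gemcitabine", "gemcitabine_regimen", 499.58),
        ("fluorouracil", "fluorouracil_regimen", 1058.81),
        ("itraconazole", "itraconazole_regimen_100", 437.73),
    ])
    def test_dose_over_clearance(self, fx, drug, regimen_name, expected):
        params, regimen = fx[drug], fx[regimen_name]
        assert pc.auc_infinity(params, regimen.total_dose) == pytest.approx(
            expected, abs=0.01)

    def test_simulated_auc_converges_to_dose_over_clearance(self, fx):
        # gemcitabine run extended to 25 terminal half-lives
        params, regimen = fx["gemcitabine"], fx["gemcitabine_regimen"]
        grid = pc.elimination_grid(params, regimen)
        traj = pc.integrate_disposition(params, regimen, grid)
        ref = pc.auc_infinity(params, regimen.total_dose)
        assert traj.auc_total == pytest.approx(ref, rel=5e-3)

    def test_auc_errors(self, gem):
        with pytest.raises(ValueError):
            pc.auc_infinity(gem, -1.0)
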