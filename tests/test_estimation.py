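"""Parameter recovery: PK fits, Hill fits, Bottom quadratic, averaging."""

import numpy as np
import pytest

import pkpdcombo as pc
from pkpdcombo.estimation import FU_AVERAGING_EXCLUSIONS, GEM_AVERAGING_EXCLUSIONS

from conftest import self_consistent

FU_SAMPLE_TIMES = (1, 2, 4, 8, 12, 18, 25, 35, 45, 60, 75, 90)
ITZ_SAMPLE_TIMES = (10, 30, 60, 90, 120, 240, 480, 960, 1920, 3840, 5760)

DESIGNS = {
    "gemcitabine": ("gemcitabine_regimen", pc.GEM_SAMPLE_TIMES),
    "fluorouracil": ("fluorouracil_regimen", FU_SAMPLE_TIMES),
    "itraconazole": ("itraconazole_regimen_100", ITZ_SAMPLE_TIMES),
}


class TestTwoCompartmentFit:
    @pytest.mark.parametrize("drug", list(DESIGNS))
    def test_noise_free_recovery(self, fx, drug):
        regimen_name, times = DESIGNS[drug]
        truth = self_consistent(fx[drug])
        samples = pc.generate_cp_profile(truth, fx[regimen_name], times,
                                         pc.NoiseModel(sd=0.0))
        fit = pc.fit_two_compartment(samples, fx[regimen_name])
        assert fit.converged
        for name, value in fit.estimates.items():
            assert value == pytest.approx(getattr(truth, name), rel=1e-3), name

    def test_noisy_recovery_of_clearance_and_central_volume(self, fx):
        truth = self_consistent(fx["gemcitabine"])
        regimen = fx["gemcitabine_regimen"]
        samples = pc.generate_cp_profile(truth, regimen, pc.GEM_SAMPLE_TIMES,
                                         pc.NoiseModel(sd=0.05, seed=1))
        fit = pc.fit_two_compartment(samples, regimen, seed=1)
        assert fit.converged
        assert fit.estimates["cl"] == pytest.approx(truth.cl, rel=0.10)
        assert fit.estimates["vd1"] == pytest.approx(truth.vd1, rel=0.10)

    @pytest.mark.parametrize("drug", list(DESIGNS))
    def test_initialization_robustness(self, fx, drug):
        """Perturbed starts (x0.5-x2 of truth) reach the same optimum."""
        regimen_name, times = DESIGNS[drug]
        truth = self_consistent(fx[drug])
        regimen = fx[regimen_name]
        samples = pc.generate_cp_profile(truth, regimen, times, pc.NoiseModel(sd=0.0))
        rng = np.random.default_rng(42)
        costs = []
        for i in range(10):
            factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=5))
            start = pc.PKParameters(*(f * v for f, v in zip(
                factors, (truth.vd1, truth.vd2, truth.cl, truth.k12, truth.k21))))
            fit = pc.fit_two_compartment(samples, regimen, init=start, n_starts=2)
            assert fit.converged
            costs.append(fit.rss)
        assert max(costs) - min(costs) < 1e-6

    def test_relative_weighting_stabilizes_bolus_fit(self, fx):
        """Without sub-minute samples an unweighted bolus fit can prefer a
        spiked profile; 1/pred^2 weighting keeps the recovery honest."""
        truth = self_consistent(fx["fluorouracil"])
        regimen = fx["fluorouracil_regimen"]
        samples = pc.generate_cp_profile(truth, regimen, FU_SAMPLE_TIMES,
                                         pc.NoiseModel(sd=0.05, seed=3))
        fit = pc.fit_two_compartment(samples, regimen, seed=3,
                                     weighting="relative")
        assert fit.estimates["cl"] == pytest.approx(truth.cl, rel=0.10)
        assert fit.estimates["vd1"] == pytest.approx(truth.vd1, rel=0.10)
        with pytest.raises(ValueError, match="weighting"):
            pc.fit_two_compartment(samples, regimen, weighting="huber")

    def test_under_determined_design_rejected(self, fx):
        regimen = fx["fluorouracil_regimen"]
        samples = [pc.ConcentrationSample(1.0, 90.0),
                   pc.ConcentrationSample(30.0, 10.0)]
        with pytest.raises(ValueError, match="distinct time points"):
            pc.fit_two_compartment(samples, regimen)

    def test_cv_reporting(self, fx):
        truth = self_consistent(fx["fluorouracil"])
        regimen = fx["fluorouracil_regimen"]
        samples = pc.generate_cp_profile(truth, regimen, FU_SAMPLE_TIMES,
                                         pc.NoiseModel(sd=0.05, seed=3))
        fit = pc.fit_two_compartment(samples, regimen, seed=3)
        assert set(fit.cv_percent) == {"vd1", "vd2", "cl", "k12", "k21"}
        assert all(v >= 0 for v in fit.cv_percent.values())
        assert fit.extras["auc"] == pytest.approx(
            pc.auc_infinity(pc.PKParameters(**fit.estimates), regimen.total_dose))


class TestHillFit:
    def test_noise_free_recovery_is_exact(self):
        truth = pc.HillCurve(bottom=12.83, top=73.07, steepness=4.37, ec50=0.0018)
        concs = np.geomspace(1e-4, 0.05, 8)
        samples = pc.generate_dose_response(truth, concs, 1,
                                            pc.NoiseModel("additive_gaussian", 0.0))
        curve, fit = pc.fit_hill(samples)
        assert fit.converged
        for name in ("bottom", "top", "steepness", "ec50"):
            assert getattr(curve, name) == pytest.approx(getattr(truth, name),
                                                         rel=1e-3), name

    def test_noisy_recovery_of_top(self, fx):
        truth = fx["fu_I4"]
        concs = list(np.geomspace(0.005, 10.0, 8) * 0.13)  # uM scaled to ug/mL
        samples = pc.generate_dose_response(
            truth, concs, 3, pc.NoiseModel("additive_gaussian", 3.0, seed=7))
        curve, fit = pc.fit_hill(samples)
        assert fit.converged
        assert abs(curve.top - truth.top) < 5.0

    def test_flat_response_rejected(self):
        samples = [pc.DoseResponseSample(conc=c, inhibition=40.0)
                   for c in (0.01, 0.1, 1.0, 10.0)]
        with pytest.raises(ValueError, match="degenerate|flat"):
            pc.fit_hill(samples)

    def test_too_few_concentrations_rejected(self):
        samples = [pc.DoseResponseSample(conc=c, inhibition=v)
                   for c, v in [(0.01, 1.0), (0.1, 20.0), (1.0, 60.0)]]
        with pytest.raises(ValueError, match="distinct concentrations"):
            pc.fit_hill(samples)


class TestBottomQuadratic:
    GEM_POINTS = [(0.0, -1.06),
                  (pc.micromolar_to_mass_conc(4.0, pc.ITRACONAZOLE_MW), 12.83),
                  (pc.micromolar_to_mass_conc(6.0, pc.ITRACONAZOLE_MW), 34.33)]
    FU_POINTS = [(0.0, -0.47),
                 (pc.micromolar_to_mass_conc(4.0, pc.ITRACONAZOLE_MW), 13.42),
                 (pc.micromolar_to_mass_conc(6.0, pc.ITRACONAZOLE_MW), 33.22)]

    @pytest.mark.parametrize("points,expected", [
        (GEM_POINTS, (2.44, -1.95, -1.06)),
        (FU_POINTS, (2.15, -1.15, -0.47)),
    ])
    def test_reproduces_published_coefficients(self, points, expected):
        mod = pc.fit_bottom_quadratic(points)
        assert (mod.a, mod.b, mod.c) == pytest.approx(expected, abs=0.005)

    def test_exact_interpolation_through_inputs(self):
        mod = pc.fit_bottom_quadratic(self.GEM_POINTS)
        for x, y in self.GEM_POINTS:
            assert abs(pc.bottom_from_itraconazole(x, mod) - y) < 1e-9

    def test_least_squares_with_extra_points(self):
        truth = (1.5, -0.5, 2.0)
        x = np.linspace(0.0, 4.0, 9)
        y = truth[0] * x**2 + truth[1] * x + truth[2]
        mod = pc.fit_bottom_quadratic(list(zip(x, y)))
        assert (mod.a, mod.b, mod.c) == pytest.approx(truth, abs=1e-9)

    def test_collinear_points_give_zero_curvature(self):
        mod = pc.fit_bottom_quadratic([(0.0, 1.0), (1.0, 2.0), (2.0, 3.0)])
        assert mod.a == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_abscissae_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pc.fit_bottom_quadratic([(0.0, 1.0), (0.0, 2.0), (2.0, 3.0)])


class TestHillAveraging:
    def gem_rows(self, fx):
        return {name: fx[name] for name in ("gem_I6", "gem_I4", "gem_I2", "gem_I0")}

    def fu_rows(self, fx):
        return {name: fx[name] for name in ("fu_I6", "fu_I4", "fu_I2", "fu_I0")}

    def test_gemcitabine_averages_with_exclusions(self, fx):
        avg = pc.average_hill_parameters(self.gem_rows(fx), GEM_AVERAGING_EXCLUSIONS)
        assert avg["top"] == pytest.approx(72.76, abs=0.005)
        assert avg["steepness"] == pytest.approx(4.67, abs=0.005)
        assert avg["ec50"] == pytest.approx(0.0021, abs=5e-5)

    def test_excluded_steepness_would_distort_average(self, fx):
        # keeping the degenerate 23.14 steepness inflates the mean to 9.29
        avg = pc.average_hill_parameters(self.gem_rows(fx))
        assert avg["steepness"] == pytest.approx(9.29, abs=0.005)

    def test_fluorouracil_averages(self, fx):
        avg = pc.average_hill_parameters(self.fu_rows(fx), FU_AVERAGING_EXCLUSIONS)
        assert avg["top"] == pytest.approx(58.65, abs=0.005)
        assert avg["steepness"] == pytest.approx(2.39, abs=0.005)
        assert avg["ec50"] == pytest.approx(0.28, abs=0.003)

    def test_single_row_identity(self, fx):
        avg = pc.average_hill_parameters({"only": fx["gem_I4"]})
        assert avg == {"top": fx["gem_I4"].top, "steepness": fx["gem_I4"].steepness,
                       "ec50": fx["gem_I4"].ec50}

    def test_all_rows_excluded_rejected(self, fx):
        with pytest.raises(ValueError, match="excluded"):
            pc.average_hill_parameters({"only": fx["gem_I4"]},
                                       frozenset({("only", "top")}))
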