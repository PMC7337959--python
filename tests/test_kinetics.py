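"""Sequential cleavage model: closed form, ODE variant, fitting, averaging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rloopkin.errors import FitError
from rloopkin.kinetics import (
    CleavageTimeCourse,
    KineticModelSpec,
    ReplicateFit,
    average_fits,
    fit_time_course,
    simulate_three_step,
    simulate_two_step,
)
from rloopkin.synth import CleavageConfig, SynthConfig, gen_time_course

from conftest import rk4_integrate


def two_step_rhs(k_a, k_b):
    def rhs(_t, y):
        return np.array([-k_a * y[0], k_a * y[0] - k_b * y[1], k_b * y[1]])

    return rhs


def three_step_rhs(kf, k_a, k_b):
    def rhs(_t, y):
        return np.array(
            [-kf * y[0], kf * y[0] - k_a * y[1], k_a * y[1] - k_b * y[2], k_b * y[2]]
        )

    return rhs


class TestSimulateTwoStep:
    def test_initial_condition(self):
        tc = simulate_two_step(0.1, 0.01, np.array([0.0]))
        assert (tc.sc[0], tc.oc[0], tc.lin[0]) == (1.0, 0.0, 0.0)

    @pytest.mark.parametrize("k", [0.01, 0.1, 1.0])
    def test_equal_rates_intermediate_peaks_at_inverse_rate(self, k):
        # degenerate branch: OC(t) = k t e^{-kt}, maximal e^{-1} at t = 1/k
        t = np.array([0.5 / k, 1.0 / k, 2.0 / k])
        tc = simulate_two_step(k, k, t)
        assert tc.oc[1] == pytest.approx(np.exp(-1), abs=1e-12)
        assert tc.oc[1] > tc.oc[0] and tc.oc[1] > tc.oc[2]

    def test_matches_fine_step_integrator(self):
        times = np.array([5.0, 20.0, 50.0])
        tc = simulate_two_step(0.1, 0.01, times)
        oracle = rk4_integrate(two_step_rhs(0.1, 0.01), [1.0, 0.0, 0.0], times)
        assert np.max(np.abs(tc.stacked().T - oracle)) < 1e-6

    @given(
        k_a=st.floats(1e-3, 1.0),
        k_b=st.floats(1e-3, 1.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_mass_conserved_and_monotone(self, k_a, k_b):
        # keep k_a*t moderate so SC does not underflow to exactly zero
        times = np.linspace(0, 5 / k_a, 40)
        tc = simulate_two_step(k_a, k_b, times)
        np.testing.assert_allclose(tc.sc + tc.oc + tc.lin, 1.0, atol=1e-9)
        assert np.all(np.diff(tc.sc) < 0)
        assert np.all(np.diff(tc.lin) > 0)

    def test_fast_second_cut_hides_intermediate(self):
        # k_b >= 50 k_a leaves no measurable nicked intermediate
        for k_a in (0.01, 0.1):
            times = np.linspace(0, 20 / k_a, 500)
            tc = simulate_two_step(k_a, 50 * k_a, times)
            assert tc.oc.max() < 0.02

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            simulate_two_step(-0.1, 0.01, np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            simulate_two_step(0.1, 0.0, np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            simulate_two_step(0.1, 0.01, np.array([1.0, 0.5]))


class TestSimulateThreeStep:
    def test_observed_sc_starts_at_one(self):
        tc = simulate_three_step(0.01, 0.14, 0.06, np.array([0.0]))
        assert tc.sc[0] == pytest.approx(1.0)

    def test_matches_fine_step_integrator(self):
        times = np.array([10.0, 60.0, 300.0])
        tc = simulate_three_step(0.01, 0.14, 0.06, times)
        oracle = rk4_integrate(
            three_step_rhs(0.01, 0.14, 0.06), [1.0, 0.0, 0.0, 0.0], times, dt=0.01
        )
        observed = np.column_stack([oracle[:, 0] + oracle[:, 1], oracle[:, 2], oracle[:, 3]])
        assert np.max(np.abs(tc.stacked().T - observed)) < 1e-6

    def test_fast_formation_limits_to_two_step(self):
        times = np.linspace(0.1, 300, 50)
        fast = simulate_three_step(1e6, 0.1, 0.01, times)
        two = simulate_two_step(0.1, 0.01, times)
        assert np.max(np.abs(fast.stacked() - two.stacked())) < 1e-4

    def test_columns_sum_to_one(self):
        times = np.linspace(0, 600, 30)
        tc = simulate_three_step(0.02, 0.14, 0.06, times)
        np.testing.assert_allclose(tc.sc + tc.oc + tc.lin, 1.0, atol=1e-7)


class TestFitTimeCourse:
    def test_recovers_noiseless_two_step(self):
        times = np.geomspace(1, 600, 12)
        tc = simulate_two_step(0.1, 0.01, times)
        fit = fit_time_course(tc, KineticModelSpec("two_step"))
        assert fit.converged
        assert fit.params["k_a"] == pytest.approx(0.1, rel=1e-4)
        assert fit.params["k_b"] == pytest.approx(0.01, rel=1e-4)

    def test_fixed_parameter_is_honored(self):
        times = np.geomspace(1, 600, 12)
        tc = simulate_two_step(0.1, 0.01, times)
        fit = fit_time_course(tc, KineticModelSpec("two_step", fixed={"k_a": 0.1}))
        assert "k_a" not in fit.params
        assert fit.params["k_b"] == pytest.approx(0.01, rel=1e-4)

    def test_three_step_refit_with_fixed_first_cut(self):
        # R-loop-limited refit: k_a clamped at 0.14/s, formation and second
        # cut float free
        times = np.geomspace(2, 600, 15)
        tc = simulate_three_step(0.01, 0.14, 0.06, times)
        spec = KineticModelSpec("three_step", fixed={"k_a": 0.14})
        fit = fit_time_course(tc, spec)
        assert fit.converged
        assert fit.params["k_formation"] == pytest.approx(0.01, rel=1e-2)
        assert fit.params["k_b"] == pytest.approx(0.06, rel=1e-2)

    def test_counts_are_normalised_per_lane(self):
        times = np.geomspace(1, 600, 12)
        frac = simulate_two_step(0.1, 0.01, times)
        counts = CleavageTimeCourse(
            "r0", times, frac.sc * 1800, frac.oc * 1800, frac.lin * 1800,
            is_fraction=False,
        )
        fit = fit_time_course(counts, KineticModelSpec("two_step"))
        assert fit.params["k_a"] == pytest.approx(0.1, rel=1e-4)

    def test_too_few_points_is_an_error(self):
        tc = simulate_two_step(0.1, 0.01, np.array([0.0, 10.0]))
        with pytest.raises(FitError):
            fit_time_course(tc, KineticModelSpec("two_step"))


class TestAverageFits:
    @staticmethod
    def _fit(rep, k_a, converged=True):
        spec = KineticModelSpec("two_step", fixed={"k_b": 0.01})
        return ReplicateFit(rep, {"k_a": k_a}, 0.0, converged, spec)

    def test_mean_and_sd(self):
        result = average_fits([self._fit("a", 0.10), self._fit("b", 0.12), self._fit("c", 0.14)])
        assert result.averaged["k_a"]["mean"] == pytest.approx(0.12)
        assert result.averaged["k_a"]["sd"] == pytest.approx(0.02)

    def test_single_replicate_flags_undefined_sd(self):
        result = average_fits([self._fit("a", 0.1)])
        assert result.single_replicate
        assert result.averaged["k_a"]["mean"] == pytest.approx(0.1)
        assert np.isnan(result.averaged["k_a"]["sd"])

    def test_non_converged_replicates_are_excluded(self):
        result = average_fits([self._fit("a", 0.1), self._fit("b", 99.0, converged=False)])
        assert result.n_converged == 1
        assert result.averaged["k_a"]["mean"] == pytest.approx(0.1)

    def test_zero_converged_is_an_error(self):
        with pytest.raises(FitError):
            average_fits([self._fit("a", 0.1, converged=False)])

    def test_poisson_count_replicates_recover_truth(self):
        # 3 scintillation replicates at 2000 counts/lane, truth (0.1, 0.01)
        config = SynthConfig(
            seed=7,
            cleavage=CleavageConfig(rates={"k_a": 0.1, "k_b": 0.01}, counts_per_lane=2000),
        )
        tcs = [gen_time_course(config, f"rep{i}", index=i) for i in range(3)]
        spec = KineticModelSpec("two_step")
        result = average_fits([fit_time_course(tc, spec) for tc in tcs])
        assert result.averaged["k_a"]["mean"] == pytest.approx(0.1, rel=0.15)
        assert result.averaged["k_b"]["mean"] == pytest.approx(0.01, rel=0.15)


class TestTimeCourseValidation:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            CleavageTimeCourse("r", [0.0, 1.0], [0.5, 0.5], [0.1, 0.1], [0.1, 0.1])

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            CleavageTimeCourse("r", [0.0], [-0.1], [0.6], [0.5])
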