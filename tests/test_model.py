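"""Mechanistic-model contracts: structure, closures, ensemble simulation."""

import numpy as np
import pytest

import emtsig as es
from emtsig.model import _make_rhs


def rhs_at(theta, pop, t, states):
    """Full RHS evaluated at given measured states (shared modifiers at rest)."""
    xR0, xP0 = es.unmeasured_steady_state(theta)
    rhs = _make_rhs(theta, pop, stimulated=False)
    y = np.concatenate([[xR0, xP0], np.asarray(states).ravel()])
    return rhs(t, y)


class TestStructure:
    def test_model_has_exactly_38_population_parameters(self):
        spec = es.build_model()
        assert spec.parameter_count == 38
        assert tuple(spec.parameter_names) == es.PARAM_NAMES

    def test_species_inventory(self):
        spec = es.build_model()
        assert set(spec.unmeasured) == {"pRAF", "PI3K*"}
        assert tuple(es.MEASURED_SPECIES) == (
            "pMEK", "ppERK", "pRSK", "pAKT", "pGSK3b", "pS6",
        )

    def test_crosstalk_edges_present(self):
        spec = es.build_model()
        assert ("PI3K*", "pRAF") in spec.crosstalk_edges
        assert ("pRSK", "pGSK3b") in spec.crosstalk_edges


class TestInputSignal:
    def test_resting_before_delay_and_jump_at_onset(self):
        assert es.input_signal(0.4, I=5.3, tau=0.5, d=0.1) == 1.0
        assert es.input_signal(-3.0, I=5.3, tau=0.5, d=0.1) == 1.0
        assert es.input_signal(0.5, I=5.3, tau=0.5, d=0.1) == pytest.approx(5.3)

    def test_decays_back_to_resting_level(self):
        assert es.input_signal(1e4, I=5.3, tau=0.5, d=0.1) == pytest.approx(1.0, abs=1e-9)

    def test_vectorized_over_time(self):
        t = np.array([-1.0, 0.5, 10.0])
        u = es.input_signal(t, I=2.0, tau=0.5, d=0.1)
        assert u.shape == (3,)
        assert u[0] == 1.0 and u[1] == pytest.approx(2.0)


class TestUnmeasuredSteadyState:
    def test_linear_case_matches_closed_form(self, presets):
        theta = presets.theta_epithelial  # hR = 1 in the reference set
        xR0, xP0 = es.unmeasured_steady_state(theta)
        a = theta.kR * xP0**theta.gc1
        assert xR0 == pytest.approx(a * theta.RT / (theta.gammaR + a), rel=1e-10)

    def test_root_residual_is_tiny_for_nonlinear_orders(self, presets):
        theta = presets.theta_epithelial.replace(hR=1.7)
        xR0, xP0 = es.unmeasured_steady_state(theta)
        resid = theta.kR * xP0**theta.gc1 * (theta.RT - xR0) - theta.gammaR * xR0**theta.hR
        scale = theta.gammaR * xR0**theta.hR
        assert abs(resid) <= 1e-10 * scale
        assert 0 < xR0 < theta.RT

    def test_pi3k_level_increases_with_production_rate(self, presets):
        theta = presets.theta_epithelial
        _, xP_lo = es.unmeasured_steady_state(theta.replace(kP=0.2))
        _, xP_hi = es.unmeasured_steady_state(theta.replace(kP=0.8))
        assert xP_hi > xP_lo


class TestCellRateClosure:
    def test_baseline_is_an_exact_steady_state(self, presets, small_epithelial_population):
        pop, _ = small_epithelial_population
        dy = rhs_at(presets.theta_epithelial, pop, t=0.0, states=pop.baseline)
        scale = np.concatenate([[1.0, 1.0], pop.totals.ravel()])
        assert np.max(np.abs(dy) / scale) < 1e-10

    def test_rates_positive_for_interior_baselines(self, small_epithelial_population):
        pop, _ = small_epithelial_population
        assert np.all(pop.gamma > 0)

    def test_closure_formula_scales_with_spare_capacity(self, presets):
        theta = presets.theta_epithelial
        totals = np.full((2, 6), 100.0)
        base = np.full((2, 6), 20.0)
        base[1, 0] = 40.0  # double this cell's baseline pMEK (h1 = 1)
        pop = es.derive_cell_rates(theta, es.CellPopulation(totals, base))
        # gamma ~ (T - x0)/x0: doubling x0 from 20 -> 40 rescales by (60/40)/(80/20)
        expected = pop.gamma[0, 0] * (60.0 / 40.0) / (80.0 / 20.0)
        assert pop.gamma[1, 0] == pytest.approx(expected, rel=1e-12)

    def test_requires_rates_before_simulation(self, presets):
        pop = es.CellPopulation(np.full((3, 6), 100.0), np.full((3, 6), 20.0))
        with pytest.raises(ValueError, match="derive_cell_rates"):
            es.simulate_ensemble(presets.theta_epithelial, pop, [5.0])


class TestEnsembleSimulation:
    times = [1.0, 3.0, 5.0, 8.0, 12.0, 15.0, 20.0, 30.0, 50.0]

    def test_resting_inputs_leave_every_cell_at_baseline(self, presets,
                                                         small_epithelial_population):
        pop, _ = small_epithelial_population
        theta = presets.theta_epithelial.replace(I1=1.0, I2=1.0)
        pop0 = es.derive_cell_rates(theta, pop)
        res = es.simulate_ensemble(theta, pop0, self.times)
        dev = np.abs(res.states - pop0.baseline[None]) / pop0.baseline[None]
        assert dev.max() < 1e-4

    def test_unstimulated_flag_freezes_the_input(self, presets,
                                                 small_epithelial_population):
        pop, _ = small_epithelial_population
        res = es.simulate_ensemble(
            presets.theta_epithelial, pop, self.times, stimulated=False
        )
        dev = np.abs(res.states - pop.baseline[None]) / pop.baseline[None]
        assert dev.max() < 1e-4

    def test_single_cell_matches_its_slice_of_the_ensemble(self, presets,
                                                           small_epithelial_population):
        pop, _ = small_epithelial_population
        res_all = es.simulate_ensemble(presets.theta_epithelial, pop, self.times)
        res_one = es.simulate_ensemble(
            presets.theta_epithelial, pop.subset(np.array([3])), self.times
        )
        np.testing.assert_allclose(
            res_one.states[:, 0, :], res_all.states[:, 3, :], rtol=1e-4, atol=1e-6
        )

    def test_conservation_zero_to_total(self, presets, small_epithelial_population):
        pop, _ = small_epithelial_population
        res = es.simulate_ensemble(presets.theta_epithelial, pop, self.times)
        assert np.all(res.states >= -1e-9)
        assert np.all(res.states <= pop.totals[None] * (1 + 1e-6))

    def test_decaying_input_relaxes_back_toward_baseline(self, presets,
                                                         small_epithelial_population):
        # pS6 turns over slowest (its closed deactivation rate is ~1e-3/min),
        # so full relaxation needs a horizon of thousands of minutes
        pop, _ = small_epithelial_population
        res = es.simulate_ensemble(presets.theta_epithelial, pop, [8000.0])
        dev = np.abs(res.states[-1] - pop.baseline) / pop.baseline
        assert dev.max() < 0.01

    def test_tolerance_refinement_converges(self, presets, small_epithelial_population):
        pop, _ = small_epithelial_population
        r1 = es.simulate_ensemble(presets.theta_epithelial, pop, self.times)
        r2 = es.simulate_ensemble(
            presets.theta_epithelial, pop, self.times, rtol=5e-7, atol_scale=5e-10
        )
        dev = np.abs(r1.states - r2.states) / (np.abs(r2.states) + 1e-9)
        assert dev.max() < 1e-4

    def test_compiled_and_reference_solvers_agree(self, presets,
                                                  small_epithelial_population):
        pop, _ = small_epithelial_population
        fast = es.simulate_ensemble(presets.theta_epithelial, pop, self.times)
        ref = es.simulate_ensemble(
            presets.theta_epithelial, pop, self.times, method="scipy"
        )
        assert fast.diagnostics["method"] == "dopri5-compiled"
        assert ref.diagnostics["method"] == "rk45-ensemble"
        dev = np.abs(fast.states - ref.states) / (np.abs(ref.states) + 1e-9)
        assert dev.max() < 1e-3

    def test_stiff_fallback_matches_fast_path_on_a_tame_problem(
        self, presets, small_epithelial_population
    ):
        # the exponential-stepping fallback trades accuracy for unconditional
        # stability; sub-percent agreement is its design tolerance
        pop, _ = small_epithelial_population
        sub = pop.subset(np.arange(10))
        fast = es.simulate_ensemble(presets.theta_epithelial, sub, [5.0, 20.0])
        stiff = es.simulate_ensemble(
            presets.theta_epithelial, sub, [5.0, 20.0], method="stiff"
        )
        assert stiff.diagnostics["method"] == "exp-euler-fallback"
        dev = np.abs(fast.states - stiff.states) / (np.abs(fast.states) + 1e-9)
        assert dev.max() < 1e-2

    def test_pre_stimulus_times_report_the_baseline(self, presets,
                                                    small_epithelial_population):
        pop, _ = small_epithelial_population
        res = es.simulate_ensemble(presets.theta_epithelial, pop, [-10.0, -5.0, 5.0])
        np.testing.assert_array_equal(res.states[0], pop.baseline)
        np.testing.assert_array_equal(res.states[1], pop.baseline)
        assert not np.allclose(res.states[2], pop.baseline)

    def test_long_format_export_round_trips_values(self, presets,
                                                   small_epithelial_population):
        pop, _ = small_epithelial_population
        sub = pop.subset(np.arange(4))
        res = es.simulate_ensemble(presets.theta_epithelial, sub, [5.0, 20.0])
        df = res.to_long_dataframe()
        assert len(df) == 2 * 4 * 6
        row = df[(df.cell == 2) & (df.time == 20.0) & (df.species == "pAKT")]
        assert row.value.item() == res.states[1, 2, 3]
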