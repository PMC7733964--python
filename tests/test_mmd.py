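"""MMD cost and optimizer contracts: kernel oracles, search behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emtsig as es
from emtsig.params import PARAM_NAMES


from _oracles import mmd2_double_loop


class TestMMD:
    def test_identical_samples_have_zero_biased_mmd(self, rng):
        A = rng.normal(size=(30, 4))
        assert es.mmd2(A, A.copy(), bandwidth=1.5) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m, d = int(rng.integers(2, 15)), int(rng.integers(2, 15)), int(rng.integers(1, 5))
        A, B = rng.normal(size=(n, d)), rng.normal(size=(m, d)) + 0.5
        sigma = float(rng.uniform(0.5, 3.0))
        for estimator in ("biased", "unbiased"):
            expected = mmd2_double_loop(A, B, sigma, estimator)
            assert es.mmd2(A, B, sigma, estimator) == pytest.approx(expected, abs=1e-12)

    def test_separated_clouds_approach_the_kernel_limit(self):
        A = np.zeros((10, 2))
        B = np.full((10, 2), 1e6)
        assert es.mmd2(A, B, bandwidth=1.0) == pytest.approx(2.0, abs=1e-12)

    def test_biased_estimate_is_nonnegative(self, rng):
        for _ in range(10):
            A, B = rng.normal(size=(20, 3)), rng.normal(size=(25, 3))
            assert es.mmd2(A, B, bandwidth=2.0) >= 0.0

    def test_input_validation(self, rng):
        A = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="dimensions"):
            es.mmd2(A, rng.normal(size=(5, 3)), 1.0)
        with pytest.raises(ValueError):
            es.mmd2(A[:1], A, 1.0)
        with pytest.raises(ValueError):
            es.mmd2(A, A, -1.0)


class TestBandwidth:
    def test_two_points_give_their_distance(self):
        X = np.array([[0.0, 0.0], [0.0, 3.0]])
        assert es.median_heuristic_bandwidth(X) == pytest.approx(3.0)

    def test_duplicated_dataset_is_invariant(self, rng):
        X = rng.normal(size=(100, 3))
        assert es.median_heuristic_bandwidth(np.vstack([X, X]), cap=10_000) == (
            pytest.approx(es.median_heuristic_bandwidth(X, cap=10_000), rel=0.1)
        )

    def test_capped_subsample_is_seed_deterministic(self, rng):
        X = rng.normal(size=(3000, 2))
        a = es.median_heuristic_bandwidth(X, cap=500, seed=3)
        b = es.median_heuristic_bandwidth(X, cap=500, seed=3)
        assert a == b

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            es.median_heuristic_bandwidth(np.ones((10, 2)))


@pytest.fixture(scope="module")
def cost_and_truth(presets, tiny_preprocessed):
    data = tiny_preprocessed["epithelial"]
    cells = es.baseline_cells(data, 60, seed=5)
    cost = es.MMDCost(data, cells, es.CostSpec(), seed=6)
    return cost, presets.theta_epithelial


class TestCostFunctional:
    def test_cost_is_nonnegative_and_deterministic(self, cost_and_truth):
        cost, theta = cost_and_truth
        f1, f2 = cost(theta), cost(theta)
        assert f1 >= 0.0 and f1 == f2

    def test_truth_beats_an_input_magnitude_off_by_one_log2(self, cost_and_truth):
        cost, theta = cost_and_truth
        assert cost(theta) < cost(theta.replace(I1=theta.I1 * 2.0))
        assert cost(theta) < cost(theta.replace(I1=theta.I1 / 2.0))
        assert cost(theta) < cost(theta.replace(I2=theta.I2 * 2.0))

    def test_single_time_weight_reduces_to_one_mmd(self, presets, tiny_preprocessed):
        data = tiny_preprocessed["epithelial"]
        cells = es.baseline_cells(data, 40, seed=5)
        full = es.MMDCost(data, cells, es.CostSpec(), seed=6)
        t_sel = full.times[2]
        weights = {t: (1.0 if t == t_sel else 0.0) for t in full.times}
        single = es.MMDCost(
            data, cells,
            es.CostSpec(bandwidth=full.bandwidth, time_weights=weights),
            seed=6,
        )
        theta = presets.theta_epithelial
        assert single(theta) == pytest.approx(full.mmd_profile(theta)[t_sel], rel=1e-12)

    def test_simulation_failure_maps_to_infinite_cost(self, cost_and_truth):
        cost, theta = cost_and_truth
        # overflowing production term: the modifier steady state is unsolvable
        broken = theta.replace(kR=1e200, RT=1e200)
        assert cost(broken) == math.inf

    def test_diagnostics_tables_cover_all_times(self, cost_and_truth):
        cost, theta = cost_and_truth
        d = cost.diagnostics(theta)
        assert set(d) == {"means", "covariances"}
        assert set(d["means"]["time"]) == set(cost.times)
        assert set(d["means"]["source"]) == {"simulated", "measured"}


class TestGlobalSearch:
    @staticmethod
    def sphere_cost(theta: es.ParameterSet) -> float:
        v = math.log10(theta.I1 / 5.3) ** 2 + math.log10(theta.I2 / 8.1) ** 2
        return 1.0 + v

    def ranges(self):
        return es.default_search_ranges()

    def test_returns_sorted_costs_and_respects_selection(self):
        kept = es.global_search(self.sphere_cost, self.ranges(), n_samples=200,
                                n_keep=20, seed=1)
        costs = [c for _, c in kept]
        assert costs == sorted(costs)
        everything = es.global_search(self.sphere_cost, self.ranges(), n_samples=200,
                                      n_keep=200, seed=1)
        assert max(costs) <= everything[20][1]

    def test_keep_all_returns_every_sample(self):
        kept = es.global_search(self.sphere_cost, self.ranges(), n_samples=50,
                                n_keep=50, seed=2)
        assert len(kept) == 50

    def test_fixed_seed_reproduces_draws(self):
        a = es.global_search(self.sphere_cost, self.ranges(), 50, 5, seed=9)
        b = es.global_search(self.sphere_cost, self.ranges(), 50, 5, seed=9)
        assert [c for _, c in a] == [c for _, c in b]
        assert a[0][0] == b[0][0]

    def test_draws_respect_ranges(self):
        seen = {}

        def record(theta):
            for n in PARAM_NAMES:
                v = getattr(theta, n)
                lo, hi = self.ranges()[n]
                assert lo - 1e-12 <= v <= hi + 1e-12
            return 1.0

        es.global_search(record, self.ranges(), 30, 5, seed=3)

    def test_all_infinite_costs_raise(self):
        with pytest.raises(RuntimeError, match="infinite"):
            es.global_search(lambda t: math.inf, self.ranges(), 20, 5, seed=1)


class TestLocalRefine:
    def test_converges_on_a_quadratic_surrogate(self, presets):
        target = presets.theta_epithelial

        def quad(theta):
            return (
                math.log10(theta.I1 / (2 * target.I1)) ** 2
                + math.log10(theta.kR / (0.5 * target.kR)) ** 2
            )

        res = es.local_refine(quad, target, round_iters=400, max_rounds=10)
        assert res.cost < 1e-6
        assert res.theta.I1 == pytest.approx(2 * target.I1, rel=1e-3)
        assert res.theta.kR == pytest.approx(0.5 * target.kR, rel=1e-3)

    def test_infinite_improvement_threshold_runs_one_round(self, presets):
        calls = {"n": 0}

        def f(theta):
            calls["n"] += 1
            return math.log10(theta.I1 / 5.0) ** 2

        res = es.local_refine(f, presets.theta_epithelial, round_iters=50,
                              improve_frac=math.inf, max_rounds=10)
        assert (res.trace["stage"] != "start").all()
        assert res.trace["round"].max() == 1

    def test_incumbent_costs_never_increase(self, presets):
        def f(theta):
            return abs(math.log10(theta.I1 / 5.0)) + 0.1 * abs(math.log10(theta.kP / 0.3))

        res = es.local_refine(f, presets.theta_epithelial, round_iters=30, max_rounds=6)
        costs = res.trace["cost"].to_numpy()
        assert np.all(np.diff(costs) <= 1e-15)

    def test_infinite_start_rejected(self, presets):
        with pytest.raises(ValueError):
            es.local_refine(lambda t: math.inf, presets.theta_epithelial)
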