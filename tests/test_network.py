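"""Partial-correlation inference: oracles, edge calls, clustering, dynamics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emtsig as es
from emtsig.data import Snapshot, SnapshotDataset


from _oracles import precision_matrix_oracle, residual_regression_oracle


class TestFisherZ:
    def test_closed_forms_and_antisymmetry(self):
        assert es.fisher_z(0.0) == 0.0
        assert es.fisher_z(0.1) == pytest.approx(0.100335, abs=1e-6)
        for r in (0.3, 0.77):
            assert es.fisher_z(-r) == -es.fisher_z(r)

    def test_rejects_unit_correlation(self):
        with pytest.raises(ValueError):
            es.fisher_z(1.0)
        with pytest.raises(ValueError):
            es.fisher_z(-1.2)


class TestPartialCorrelation:
    def test_self_correlation_with_empty_conditioning_set(self, rng):
        x = rng.normal(size=50)
        assert es.partial_correlation(x, x) == pytest.approx(1.0)

    def test_markov_chain_conditional_independence(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = 0.8 * x + 0.6 * rng.normal(size=n)
        w = 0.8 * y + 0.6 * rng.normal(size=n)
        rho = es.partial_correlation(x, w, y[:, None])
        assert abs(rho) < 0.05

    def test_matches_residual_regression_oracle(self, rng):
        for _ in range(20):
            n, k = 40, 3
            Z = rng.normal(size=(n, k))
            x = Z @ rng.normal(size=k) + rng.normal(size=n)
            y = Z @ rng.normal(size=k) + rng.normal(size=n)
            expected = residual_regression_oracle(x, y, Z)
            assert es.partial_correlation(x, y, Z) == pytest.approx(expected, abs=1e-10)

    def test_zero_residual_variance_warns_and_returns_nan(self, rng):
        z = rng.normal(size=30)
        x = 2.0 * z + 1.0  # exact linear function of the conditioning set
        y = rng.normal(size=30)
        with pytest.warns(UserWarning, match="zero residual variance"):
            out = es.partial_correlation(x, y, z[:, None])
        assert np.isnan(out)

    def test_rank_deficient_conditioning_warns(self, rng):
        z = rng.normal(size=30)
        Z = np.column_stack([z, z])  # duplicated column
        x, y = rng.normal(size=30), rng.normal(size=30)
        with pytest.warns(UserWarning, match="rank deficient"):
            es.partial_correlation(x, y, Z)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            es.partial_correlation([1.0, 2.0], [2.0, 3.0])


class TestPartialCorrelationMatrix:
    def test_two_variables_reduce_to_pearson(self, rng):
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": y})
        net = es.partial_correlation_matrix(df)
        assert net.rho[0, 1] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_both_oracles_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 7))
        n = int(rng.integers(p + 10, 200))
        A = rng.normal(size=(p, p))
        X = rng.normal(size=(n, p)) @ A.T
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])
        net = es.partial_correlation_matrix(df)
        R_prec = precision_matrix_oracle(X)
        np.testing.assert_allclose(net.rho, R_prec, atol=1e-8)
        for i in range(p):
            for j in range(i + 1, p):
                others = [k for k in range(p) if k not in (i, j)]
                expected = residual_regression_oracle(X[:, i], X[:, j], X[:, others])
                assert net.rho[i, j] == pytest.approx(expected, abs=1e-10)

    def test_cascade_recovery_calls_exactly_the_chain_edges(self):
        df = es.linear_gaussian_cascade(20_000, seed=33)
        snap = Snapshot(data=df, time=0.0, replicate=1)
        logged = es.log_transform(snap, "log1p")
        net = es.partial_correlation_matrix(logged, list(df.columns), threshold=0.1)
        expected = {
            frozenset(e)
            for e in [("pMEK", "ppERK"), ("ppERK", "pRSK"), ("pRSK", "pS6"),
                      ("pAKT", "pGSK3b")]
        }
        assert {frozenset(e) for e in net.edges} == expected

    def test_edge_count_monotone_in_threshold(self, rng):
        X = rng.normal(size=(500, 5)) @ rng.normal(size=(5, 5))
        df = pd.DataFrame(X - X.min() + 1.0, columns=list("abcde"))
        counts = []
        for thr in (0.05, 0.1, 0.2, 0.4, 0.8):
            net = es.partial_correlation_matrix(df, threshold=thr)
            counts.append(len(net.edges))
        assert counts == sorted(counts, reverse=True)

    def test_edge_table_flags_threshold(self, rng):
        X = rng.normal(size=(300, 4))
        net = es.partial_correlation_matrix(pd.DataFrame(X, columns=list("abcd")))
        table = net.edge_table()
        assert len(table) == 6
        assert (table.passes_threshold == (table.rho.abs() >= 0.1)).all()
        np.testing.assert_allclose(table.z, np.arctanh(table.rho), atol=1e-12)


class TestClusterOrder:
    def test_two_variables_keep_input_order(self, rng):
        X = rng.normal(size=(100, 2))
        net = es.partial_correlation_matrix(pd.DataFrame(X, columns=["b", "a"]))
        assert es.cluster_order(net) == ["b", "a"]

    def test_correlated_blocks_stay_adjacent(self, rng):
        n = 2000
        u, v = rng.normal(size=n), rng.normal(size=n)
        X = np.column_stack(
            [u + 0.05 * rng.normal(size=n), v + 0.05 * rng.normal(size=n),
             u + 0.05 * rng.normal(size=n), v + 0.05 * rng.normal(size=n)]
        )
        net = es.partial_correlation_matrix(pd.DataFrame(X, columns=["u1", "v1", "u2", "v2"]))
        order = es.cluster_order(net)
        iu1, iu2 = order.index("u1"), order.index("u2")
        iv1, iv2 = order.index("v1"), order.index("v2")
        assert abs(iu1 - iu2) == 1 and abs(iv1 - iv2) == 1

    def test_permuting_variables_preserves_partition(self, rng):
        n = 3000
        u, v = rng.normal(size=n), rng.normal(size=n)
        cols = {
            "u1": u + 0.1 * rng.normal(size=n),
            "u2": u + 0.1 * rng.normal(size=n),
            "v1": v + 0.1 * rng.normal(size=n),
            "v2": v + 0.1 * rng.normal(size=n),
        }
        df = pd.DataFrame(cols)
        order1 = es.cluster_order(es.partial_correlation_matrix(df))
        df2 = df[["v2", "u1", "v1", "u2"]]
        order2 = es.cluster_order(es.partial_correlation_matrix(df2))

        def partition(order):
            pairs = set()
            for a, b in zip(order[:-1], order[1:]):
                if a[0] == b[0]:
                    pairs.add(frozenset((a, b)))
            return pairs

        assert partition(order1) == partition(order2)


class TestEdgeDynamics:
    def _dataset(self, rng, identical=False, n_reps=3):
        snaps = []
        base = rng.normal(size=(200, 3))
        for t in (0.0, 5.0):
            for rep in range(1, n_reps + 1):
                X = base if identical else rng.normal(size=(200, 3))
                Y = np.column_stack([X[:, 0], 0.8 * X[:, 0] + 0.6 * X[:, 1], X[:, 2]])
                df = pd.DataFrame(Y - Y.min() + 1.0, columns=["a", "b", "c"])
                snaps.append(Snapshot(data=df, time=t, replicate=rep))
        return SnapshotDataset(snaps)

    def test_identical_replicates_have_zero_sd(self, rng):
        d = self._dataset(rng, identical=True)
        _, summary = es.edge_dynamics_by_timepoint(d, [("a", "b")], ["a", "b", "c"])
        assert (summary["sd"].abs() < 1e-12).all()

    def test_single_replicate_reports_missing_sd(self, rng):
        d = self._dataset(rng, n_reps=1)
        _, summary = es.edge_dynamics_by_timepoint(d, [("a", "b")], ["a", "b", "c"])
        assert summary["sd"].isna().all()

    def test_stationary_dependence_gives_flat_profile(self, rng):
        d = self._dataset(rng)
        table, summary = es.edge_dynamics_by_timepoint(d, [("a", "b")], ["a", "b", "c"])
        means = summary["mean"].to_numpy()
        assert np.ptp(means) < 0.1
        assert len(table) == 2 * 3  # 2 time points x 3 replicates
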