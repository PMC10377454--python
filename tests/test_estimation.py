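"""Pearson/phi matrix, nodewise eLASSO estimation, layout."""

import numpy as np
import pytest
import statsmodels.api as sm

import symptomnet as sn
from symptomnet.datasets import SymptomDataset
from symptomnet.estimation import EstimatorConfig

from conftest import make_params, sample_from


class TestPearson:
    def test_duplicated_column_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 2, 200)
        data = SymptomDataset(np.column_stack([col, col, rng.integers(0, 2, 200)]))
        r = sn.pearson_matrix(data).values
        assert r[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(1)
        data = SymptomDataset(rng.integers(0, 2, (100_000, 2)))
        r = sn.pearson_matrix(data).values
        assert abs(r[0, 1]) < 0.02

    def test_phi_formula_on_two_by_two_table(self):
        # (a,b,c,d) = (30,10,10,30): phi = (ad-bc)/sqrt(...) = 0.5 by hand
        x = np.array([[1, 1]] * 30 + [[1, 0]] * 10 + [[0, 1]] * 10 + [[0, 0]] * 30)
        r = sn.pearson_matrix(SymptomDataset(x)).values
        assert r[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_zero_variance_column_flagged(self):
        x = np.column_stack([np.ones(50, dtype=int), np.arange(50) % 2])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = sn.pearson_matrix(SymptomDataset(x)).values
        assert np.isnan(r[0, 1])
        assert r[0, 0] == 1.0


class TestFitIsing:
    def test_independent_columns_give_empty_network(self):
        rng = np.random.default_rng(2)
        data = SymptomDataset(rng.integers(0, 2, (10_000, 5)))
        net = sn.fit_ising(data)
        assert np.all(net.weights == 0)

    def test_strong_edge_recovered_with_few_false_positives(self):
        edges = {(0, 1): 1.5}
        truth = make_params([f"s{i}" for i in range(9)], np.full(9, -0.5), edges)
        recovered = 0
        fps = []
        for seed in range(10):
            data = sample_from(truth, 2000, seed=100 + seed)
            net = sn.fit_ising(data)
            if net.weights[0, 1] > 0:
                recovered += 1
            fps.append((net.weights != 0).sum() // 2 - (net.weights[0, 1] != 0))
        assert recovered == 10
        assert np.mean(fps) <= 2

    def test_false_edge_rate_under_global_null(self):
        truth = make_params([f"s{i}" for i in range(9)], np.full(9, 0.2), {})
        fps = []
        for seed in range(20):
            data = sample_from(truth, 2000, seed=300 + seed)
            net = sn.fit_ising(data, gamma=0.25)
            fps.append((net.weights != 0).sum() // 2)
        assert np.mean(fps) <= 1

    def test_and_rule_never_denser_than_or_rule(self, nine_node_cohort):
        net_and = sn.fit_ising(nine_node_cohort, rule="AND")
        net_or = sn.fit_ising(nine_node_cohort, rule="OR")
        and_edges = net_and.weights != 0
        or_edges = net_or.weights != 0
        assert (or_edges | and_edges).sum() == or_edges.sum()

    def test_nodewise_support_matches_unpenalized_refit_in_sign(self):
        truth = make_params(
            ["a", "b", "c", "d"], [0.0, -0.3, 0.2, 0.0], {(0, 1): 1.2, (2, 3): -1.0}
        )
        data = sample_from(truth, 3000, seed=17)
        net = sn.fit_ising(data)
        x = data.values.astype(float)
        for i in range(4):
            others = [j for j in range(4) if j != i]
            sel = [j for j in others if net.weights[i, j] != 0]
            if not sel:
                continue
            X = sm.add_constant(x[:, sel])
            refit = sm.Logit(x[:, i], X).fit(disp=0)
            for pos, j in enumerate(sel):
                assert np.sign(refit.params[1 + pos]) == np.sign(net.weights[i, j])

    def test_zero_variance_node_kept_without_edges(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, (500, 4))
        x[:, 0] = 1
        with pytest.warns(UserWarning, match="zero-variance"):
            net = sn.fit_ising(SymptomDataset(x))
        assert np.all(net.weights[0] == 0)
        assert net.p == 4

    def test_small_sample_warns(self):
        rng = np.random.default_rng(4)
        data = SymptomDataset(rng.integers(0, 2, (30, 5)))
        with pytest.warns(UserWarning, match="below the recommended"):
            sn.fit_ising(data)

    def test_estimator_config_validation(self):
        with pytest.raises(ValueError, match="rule"):
            EstimatorConfig(rule="XOR")
        with pytest.raises(ValueError, match="lambda_min_ratio"):
            EstimatorConfig(lambda_min_ratio=2.0)

    def test_network_serialization_round_trip(self, tmp_path, nine_node_cohort):
        net = sn.fit_ising(nine_node_cohort)
        path = tmp_path / "net.json"
        net.to_json(path)
        back = sn.IsingNetwork.from_json(path)
        assert np.array_equal(back.weights, net.weights)
        assert back.labels == net.labels
        net.to_edgelist_tsv(tmp_path / "edges.tsv")
        assert (tmp_path / "edges.tsv").read_text().startswith("node_i\tnode_j\tweight")


class TestSolverCrossCheck:
    def test_l1_path_matches_liblinear(self):
        """Penalized path solutions agree with an independent L1 logistic
        implementation (sklearn/liblinear) to 1e-3 across the path."""
        from sklearn.linear_model import LogisticRegression

        from symptomnet._kernels import logistic_lasso_path
        from symptomnet.estimation import _aggregate_states

        truth = make_params(
            [f"s{i}" for i in range(5)],
            np.linspace(-1, 1, 5),
            {(0, 1): 1.0, (2, 3): -0.8},
        )
        data = sample_from(truth, 1500, seed=11)
        states, counts = _aggregate_states(data.values)
        n = counts.sum()
        cols = np.array([1, 2, 3, 4])
        X, y = states[:, cols], np.ascontiguousarray(states[:, 0])
        ybar = (counts * y).sum() / n
        lam_max = np.max(np.abs((counts * (y - ybar)) @ X)) / n
        lambdas = np.geomspace(lam_max, 0.01 * lam_max, 8)
        mu = (counts @ X) / n
        XcT = np.ascontiguousarray((X - mu).T)
        ints, betas, _ = logistic_lasso_path(XcT, y, counts, lambdas, 1e-8, 500)

        Xfull = np.repeat(X, counts.astype(int), axis=0)
        yfull = np.repeat(y, counts.astype(int))
        for k in (2, 5, 7):
            ref = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", C=1.0 / (n * lambdas[k]),
                intercept_scaling=1e4, tol=1e-10, max_iter=10_000,
            ).fit(Xfull, yfull)
            assert np.allclose(betas[k], ref.coef_[0], atol=1e-3)
            assert ints[k] - betas[k] @ mu == pytest.approx(
                float(ref.intercept_[0]), abs=1e-3
            )


class TestConsistency:
    def test_recovered_weights_approach_truth_with_n(self, nine_node_truth):
        """RMSE of the weight matrix decreases monotonically in n."""
        iu = np.triu_indices(9, 1)
        rmse = []
        for n in (500, 2000, 8000):
            errs = []
            for seed in range(8):
                data = sample_from(nine_node_truth, n, seed=1000 * n + seed)
                net = sn.fit_ising(data)
                errs.append(
                    np.mean((net.weights[iu] - nine_node_truth.weights[iu]) ** 2)
                )
            rmse.append(np.sqrt(np.mean(errs)))
        assert rmse[0] > rmse[1] > rmse[2]


class TestLayout:
    def test_deterministic_given_seed(self, nine_node_cohort):
        net = sn.fit_ising(nine_node_cohort)
        a = sn.fr_layout(net, seed=5)
        b = sn.fr_layout(net, seed=5)
        assert np.array_equal(a.xy, b.xy)

    def test_positive_edge_attracts(self):
        connected = sn.IsingNetwork(["a", "b"], np.zeros(2),
                                    np.array([[0.0, 0.8], [0.8, 0.0]]))
        apart = sn.IsingNetwork(["a", "b"], np.zeros(2), np.zeros((2, 2)))
        d_conn = np.linalg.norm(np.diff(sn.fr_layout(connected, seed=1).xy, axis=0))
        d_apart = np.linalg.norm(np.diff(sn.fr_layout(apart, seed=1).xy, axis=0))
        assert d_conn < d_apart

    def test_star_hub_is_central(self):
        p = 6
        w = np.zeros((p, p))
        w[0, 1:] = w[1:, 0] = 0.7
        net = sn.IsingNetwork([f"s{i}" for i in range(p)], np.zeros(p), w)
        xy = sn.fr_layout(net, seed=3).xy
        centroid = xy[1:].mean(axis=0)
        hub_dist = np.linalg.norm(xy[0] - centroid)
        leaf_dists = np.linalg.norm(xy[1:] - centroid, axis=1)
        assert hub_dist < leaf_dists.min()
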