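"""Synthetic-cohort generator: exact enumeration, sampling, conditioning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import symptomnet as sn
from symptomnet.simulate import ENUMERATION_GUARD, _enumerate

from conftest import make_params, sample_from


class TestEnumerate:
    def test_independent_symmetric_model_is_uniform(self):
        params = make_params(["a", "b"], [0.0, 0.0], {})
        df = sn.enumerate_distribution(params)
        assert np.allclose(df["probability"], 0.25)

    def test_logistic_marginal_with_zero_coupling(self):
        # tau = log 3 on an isolated node gives P(x=1) = 0.75
        params = make_params(["a", "b"], [np.log(3.0), 0.0], {})
        df = sn.enumerate_distribution(params)
        p_a = df.loc[df["a"] == 1, "probability"].sum()
        assert p_a == pytest.approx(0.75, abs=1e-12)

    def test_matches_hand_enumeration_with_one_edge(self):
        # independent brute force over the 8 states of a 3-node model
        params = make_params(["a", "b", "c"], [0.0, 0.0, 0.0], {(0, 1): 1.0})
        pots = []
        states = [(i, j, k) for k in (0, 1) for j in (0, 1) for i in (0, 1)]
        for x in states:
            pots.append(np.exp(1.0 * x[0] * x[1]))
        expected = np.array(pots) / np.sum(pots)
        df = sn.enumerate_distribution(params)
        got = {tuple(row[:3].astype(int)): row[3] for row in df.to_numpy()}
        for x, e in zip(states, expected):
            assert got[x] == pytest.approx(e, abs=1e-12)
        p11 = sum(e for x, e in zip(states, expected) if x[0] == 1 and x[1] == 1)
        assert p11 > 0.25

    def test_enumeration_guard_refuses_large_p(self):
        p = ENUMERATION_GUARD + 1
        params = make_params([f"s{i}" for i in range(p)], np.zeros(p), {})
        with pytest.raises(ValueError, match="[Gg]ibbs"):
            sn.enumerate_distribution(params)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_probabilities_nonnegative_and_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 6))
        w = rng.normal(0, 1, (p, p))
        w = np.triu(w, 1)
        w = w + w.T
        params = sn.IsingParameters(
            [f"s{i}" for i in range(p)], rng.normal(0, 1.5, p), w
        )
        _, probs = _enumerate(params)
        assert (probs >= 0).all()
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestParameterValidation:
    def test_asymmetric_weights_rejected(self):
        w = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            sn.IsingParameters(["a", "b"], np.zeros(2), w)

    def test_nonzero_diagonal_rejected(self):
        w = np.eye(2)
        with pytest.raises(ValueError, match="diagonal"):
            sn.IsingParameters(["a", "b"], np.zeros(2), w)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            sn.IsingParameters(["a", "a"], np.zeros(2), np.zeros((2, 2)))

    def test_json_round_trip(self, tmp_path, nine_node_truth):
        path = tmp_path / "params.json"
        nine_node_truth.to_json(path)
        back = sn.IsingParameters.from_json(path)
        assert back.labels == nine_node_truth.labels
        assert np.array_equal(back.thresholds, nine_node_truth.thresholds)
        assert np.array_equal(back.weights, nine_node_truth.weights)


class TestSampleCohort:
    def test_dsm_constraint_holds_by_construction(self):
        params = sn.paper_like_parameters()["PPD"]
        spec = sn.CohortSpec(
            {"PPD": 300}, {"PPD": params}, dsm_constraint=True, seed=5
        )
        data = sn.sample_cohort(spec)["PPD"]
        sums = data.values.sum(axis=1)
        assert (sums >= 5).all()
        assert (data.values[:, :2].sum(axis=1) >= 1).all()

    def test_empirical_frequencies_match_enumeration(self, chain3):
        n = 50_000
        data = sample_from(chain3, n, seed=11)
        states, probs = _enumerate(chain3)
        codes = data.values @ (1 << np.arange(3))
        counts = np.bincount(codes, minlength=8)
        se = np.sqrt(probs * (1 - probs) / n)
        assert (np.abs(counts / n - probs) <= 3 * se + 1e-9).all()

    def test_group_weight_difference_shows_in_odds_ratios(self):
        # stronger coupling must raise the empirical pairwise odds ratio
        pa = make_params(["a", "b"], [0.0, 0.0], {(0, 1): 0.0})
        pb = make_params(["a", "b"], [0.0, 0.0], {(0, 1): 1.5})
        spec = sn.CohortSpec(
            {"A": 20_000, "B": 20_000}, {"A": pa, "B": pb}, seed=13
        )
        out = sn.sample_cohort(spec)

        def emp_or(d):
            x = d.values
            n11 = ((x[:, 0] == 1) & (x[:, 1] == 1)).sum()
            n00 = ((x[:, 0] == 0) & (x[:, 1] == 0)).sum()
            n10 = ((x[:, 0] == 1) & (x[:, 1] == 0)).sum()
            n01 = ((x[:, 0] == 0) & (x[:, 1] == 1)).sum()
            return (n11 * n00) / (n10 * n01)

        assert emp_or(out["B"]) > emp_or(out["A"])

    def test_zero_mass_constraint_raises(self, chain3):
        spec = sn.CohortSpec(
            {"g": 10},
            {"g": chain3},
            dsm_constraint=True,
            k_min_symptoms=2,
            cardinal_indices=(),
            seed=1,
        )
        with pytest.raises(ValueError, match="zero probability"):
            sn.sample_cohort(spec)

    def test_seed_determinism(self, nine_node_truth):
        spec = dict(
            n_per_group={"g": 500},
            params_per_group={"g": nine_node_truth},
            dsm_constraint=True,
            seed=42,
        )
        a = sn.sample_cohort(sn.CohortSpec(**spec))["g"]
        b = sn.sample_cohort(sn.CohortSpec(**spec))["g"]
        assert np.array_equal(a.values, b.values)

    def test_conditioning_equals_filtering_in_distribution(self):
        # conditioned sampling vs unconditioned-then-filter: state
        # frequencies agree at large n
        params = make_params(
            ["a", "b", "c", "d"], [0.3, -0.2, 0.1, 0.0], {(0, 1): 0.8, (2, 3): -0.5}
        )
        n = 40_000
        cond = sample_from(
            params, n, seed=3, dsm_constraint=True, k_min_symptoms=2,
            cardinal_indices=(0,),
        )
        raw = sample_from(params, 4 * n, seed=4)
        keep = (raw.values.sum(axis=1) >= 2) & (raw.values[:, 0] == 1)
        filt = raw.values[keep]
        f_cond = np.bincount(cond.values @ (1 << np.arange(4)), minlength=16) / n
        f_filt = np.bincount(filt @ (1 << np.arange(4)), minlength=16) / len(filt)
        assert np.abs(f_cond - f_filt).max() < 0.01


class TestGibbs:
    def test_independent_sites_match_logistic_marginals(self):
        params = make_params(["a", "b", "c"], [-1.0, 0.0, 1.0], {})
        data = sn.gibbs_sample(params, n=20_000, burn_in=200, thin=2, seed=7)
        want = 1 / (1 + np.exp(-params.thresholds))
        assert np.abs(data.values.mean(axis=0) - want).max() < 0.02

    def test_seed_determinism(self, chain3):
        a = sn.gibbs_sample(chain3, n=500, seed=9)
        b = sn.gibbs_sample(chain3, n=500, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_argument_validation(self, chain3):
        with pytest.raises(ValueError):
            sn.gibbs_sample(chain3, n=0)


class TestCalibration:
    def test_thresholds_hit_target_marginals(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        target = np.array([0.9, 0.7, 0.5, 0.3])
        params = sn.calibrate_thresholds(w, target)
        assert np.abs(sn.exact_marginals(params) - target).max() < 1e-6

    def test_conditioned_calibration(self):
        w = np.zeros((5, 5))
        target = np.array([0.9, 0.8, 0.6, 0.6, 0.5])
        params = sn.calibrate_thresholds(
            w, target, dsm_constraint=True, k_min_symptoms=3,
            cardinal_indices=(0, 1),
        )
        got = sn.exact_marginals(
            params, dsm_constraint=True, k_min_symptoms=3, cardinal_indices=(0, 1)
        )
        assert np.abs(got - target).max() < 1e-6

    def test_paper_like_cohorts_shapes_and_ordering(self):
        cohorts = sn.paper_like_cohorts(n_mde=300, n_ppd=200, seed=2)
        assert cohorts["MDE"].n == 300 and cohorts["PPD"].n == 200
        freq = cohorts["PPD"].values.mean(axis=0)
        labels = cohorts["PPD"].labels
        top3 = {labels[i] for i in np.argsort(freq)[-3:]}
        assert top3 == {"fatigue", "sadness", "anhedonia"}
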