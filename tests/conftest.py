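"""Shared fixtures: small Ising ground truths and sampled cohorts."""

import numpy as np
import pytest
from hypothesis import settings

from symptomnet import CohortSpec, IsingParameters, sample_cohort

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


def make_params(labels, thresholds, edges):
    p = len(labels)
    w = np.zeros((p, p))
    for (i, j), v in edges.items():
        w[i, j] = w[j, i] = v
    return IsingParameters(labels, np.asarray(thresholds, dtype=float), w)


@pytest.fixture(scope="session")
def chain3():
    """Three symptoms, one strong edge: tiny, exactly enumerable."""
    return make_params(["a", "b", "c"], [0.0, 0.0, 0.0], {(0, 1): 1.0})


@pytest.fixture(scope="session")
def nine_node_truth():
    """Fixed 9-node ground truth with 6 strong edges and mid-range marginals.

    Used for sampler validity, parameter recovery and the permutation-test
    calibration: every edge is strong enough to be recoverable at n=2000.
    """
    edges = {
        (0, 1): 1.2,
        (1, 2): -1.0,
        (2, 3): 1.0,
        (4, 5): 1.4,
        (5, 6): -1.2,
        (7, 8): 1.1,
    }
    tau = [-0.6, -0.4, 0.3, -0.5, -0.8, -0.3, 0.4, -0.4, 0.1]
    return make_params([f"s{i}" for i in range(9)], tau, edges)


@pytest.fixture(scope="session")
def nine_node_cohort(nine_node_truth):
    """n=2000 sample from the fixed truth (unconstrained)."""
    spec = CohortSpec(
        {"g": 2000}, {"g": nine_node_truth}, dsm_constraint=False, seed=20260924
    )
    return sample_cohort(spec)["g"]


def sample_from(params, n, seed, **kw):
    spec = CohortSpec({"g": n}, {"g": params}, seed=seed, **kw)
    return sample_cohort(spec)["g"]
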