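"""Permutation-based comparison of two symptom networks (NCT).

Two global invariance statistics are computed from networks estimated
separately per group with identical settings:

- network structure invariance  M = max_{i<j} |w_a_ij - w_b_ij|
- global strength invariance    S = | sum_{i<j} |w_a_ij| - sum_{i<j} |w_b_ij| |

The null distribution pools all participants, randomly reassigns group
membership preserving group sizes, refits both networks and recomputes M
and S for each permutation; p-values use the add-one rule
p = (1 + #{null >= observed}) / (1 + n_perm).

Implementation note: pooled rows are sorted canonically and each
permutation draws the smaller group as a subset, so swapping the two input
datasets leaves M, S and the p-values exactly unchanged (both statistics
are symmetric in the groups).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import SymptomDataset
from .estimation import EstimatorConfig, IsingNetwork, _aggregate_states, _fit_from_states


def _upper(w: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(w.shape[0], 1)
    return w[iu]


def global_strength(network: IsingNetwork) -> float:
    """Sum of absolute edge weights over unordered node pairs."""
    return float(np.abs(_upper(network.weights)).sum())


def _m_statistic(wa: np.ndarray, wb: np.ndarray) -> float:
    return float(np.max(np.abs(_upper(wa) - _upper(wb))))


@dataclass
class NCTResult:
    m_observed: float
    p_m: float
    s_observed: float
    p_s: float
    global_strengths: dict[str, float]
    null_m: np.ndarray
    null_s: np.ndarray
    n_perm: int
    seed: int
    edge_p_values: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "m_observed": self.m_observed,
            "p_m": self.p_m,
            "s_observed": self.s_observed,
            "p_s": self.p_s,
            "global_strengths": self.global_strengths,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def null_to_csv(self, path) -> None:
        pd.DataFrame({"null_m": self.null_m, "null_s": self.null_s}).to_csv(
            path, index=False
        )


def nct(
    data_a: SymptomDataset,
    data_b: SymptomDataset,
    n_perm: int = 1000,
    seed: int = 0,
    config: EstimatorConfig | None = None,
    edge_tests: bool = False,
) -> NCTResult:
    """Permutation test of network-structure and global-strength invariance.

    Parameters
    ----------
    data_a, data_b
        Binary datasets with identical symptom labels and ordering.
    n_perm
        Number of label permutations for the null distributions.
    edge_tests
        Also compute per-edge difference p-values (exploratory; off by
        default because only the global tests are headline output).
    """
    if data_a.labels != data_b.labels:
        raise ValueError("both datasets must share symptom labels and ordering")
    cfg = config or EstimatorConfig()
    labels = data_a.labels

    def fit(values: np.ndarray) -> IsingNetwork:
        states, counts = _aggregate_states(values)
        return _fit_from_states(states, counts, labels, cfg)

    net_a = fit(data_a.values)
    net_b = fit(data_b.values)
    m_obs = _m_statistic(net_a.weights, net_b.weights)
    gs_a, gs_b = global_strength(net_a), global_strength(net_b)
    name_a = data_a.group or "a"
    name_b = data_b.group or "b"
    if name_b == name_a:
        name_a, name_b = f"{name_a}_1", f"{name_b}_2"
    gs = {name_a: gs_a, name_b: gs_b}
    s_obs = float(abs(gs_a - gs_b))
    edge_diff_obs = np.abs(_upper(net_a.weights) - _upper(net_b.weights))

    # canonical pooling for exact swap symmetry
    pooled = np.vstack([data_a.values, data_b.values])
    order = np.lexsort(pooled.T[::-1])
    pooled = pooled[order]
    n_total = pooled.shape[0]
    n_small = min(data_a.n, data_b.n)

    rng = np.random.default_rng(seed)
    null_m = np.empty(n_perm)
    null_s = np.empty(n_perm)
    iu_size = edge_diff_obs.size
    edge_ge = np.zeros(iu_size)
    for b in range(n_perm):
        for _attempt in range(3):
            perm = rng.permutation(n_total)
            try:
                net_1 = fit(pooled[perm[:n_small]])
                net_2 = fit(pooled[perm[n_small:]])
                break
            except Exception:
                continue
        else:
            raise RuntimeError("permutation refit failed repeatedly")
        null_m[b] = _m_statistic(net_1.weights, net_2.weights)
        null_s[b] = abs(global_strength(net_1) - global_strength(net_2))
        if edge_tests:
            edge_ge += (
                np.abs(_upper(net_1.weights) - _upper(net_2.weights))
                >= edge_diff_obs
            )

    p_m = float((1 + np.sum(null_m >= m_obs)) / (1 + n_perm))
    p_s = float((1 + np.sum(null_s >= s_obs)) / (1 + n_perm))

    edge_df = None
    if edge_tests:
        iu = np.triu_indices(len(labels), 1)
        edge_df = pd.DataFrame(
            {
                "node_i": [labels[i] for i in iu[0]],
                "node_j": [labels[j] for j in iu[1]],
                "abs_difference": edge_diff_obs,
                "p_value": (1 + edge_ge) / (1 + n_perm),
            }
        )
    return NCTResult(
        m_obs, p_m, s_obs, p_s, gs, null_m, null_s, n_perm, seed, edge_df
    )
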