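"""Centrality and small-world measures on weighted signed symptom networks.

Local centrality follows the psychometric-network conventions:

- Strength: s_i = sum_j |w_ij|, the weighted number of connections.
- Expected influence: ei_i = sum_j w_ij, the signed one-step sum.
- Closeness and betweenness use geodesics with edge length 1/|w_ij|
  (stronger edges are shorter); closeness is the inverse mean distance to
  reachable nodes, scaled by (reachable-1)/(p-1) on disconnected graphs,
  and betweenness uses Brandes accounting with fractional credit for tied
  geodesics.

Figure-style standardization is the z-score across nodes (sample SD).

The global small-world index compares clustering and mean path length
against Erdos-Renyi graphs with matched node and edge counts:
sigma = (C / <C_rand>) / (L / <L_rand>); an index above 1 is read as
small-world organisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .estimation import IsingNetwork

METRICS = ("strength", "closeness", "betweenness", "expected_influence")


def _length_graph(network: IsingNetwork) -> nx.Graph:
    """Graph with 1/|w| as 'length' (and |w| kept as 'weight')."""
    g = nx.Graph()
    g.add_nodes_from(range(network.p))
    p = network.p
    for i in range(p):
        for j in range(i + 1, p):
            w = network.weights[i, j]
            if w != 0:
                g.add_edge(i, j, weight=abs(w), length=1.0 / abs(w))
    return g


def strength(network: IsingNetwork) -> np.ndarray:
    return np.abs(network.weights).sum(axis=1)


def expected_influence(network: IsingNetwork) -> np.ndarray:
    return network.weights.sum(axis=1)


def closeness(network: IsingNetwork) -> np.ndarray:
    g = _length_graph(network)
    cc = nx.closeness_centrality(g, distance="length", wf_improved=True)
    return np.array([cc[i] for i in range(network.p)])


def betweenness(network: IsingNetwork) -> np.ndarray:
    g = _length_graph(network)
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(network.p)])


_METRIC_FUNCS = {
    "strength": strength,
    "closeness": closeness,
    "betweenness": betweenness,
    "expected_influence": expected_influence,
}


@dataclass
class CentralityTable:
    """Raw and z-standardized centralities, one row per node."""

    labels: list[str]
    raw: pd.DataFrame  # index: labels, columns: METRICS
    z: pd.DataFrame

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for metric in self.raw.columns:
            for lab in self.labels:
                rows.append(
                    (lab, metric, self.raw.loc[lab, metric], self.z.loc[lab, metric])
                )
        return pd.DataFrame(rows, columns=["node", "metric", "raw", "z"])

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)


def standardize(values: np.ndarray) -> np.ndarray:
    """z-scores across nodes with sample SD; all-zero if the SD is zero."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two nodes to standardize")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("constant metric: z-scores set to 0", stacklevel=2)
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def centrality_table(
    network: IsingNetwork, metrics: tuple[str, ...] = METRICS
) -> CentralityTable:
    """Compute the requested centralities, raw and z-standardized."""
    unknown = set(metrics) - set(_METRIC_FUNCS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    raw = pd.DataFrame(
        {m: _METRIC_FUNCS[m](network) for m in metrics}, index=network.labels
    )
    z = raw.apply(lambda col: standardize(col.to_numpy()), axis=0)
    z = pd.DataFrame(z, index=network.labels, columns=list(metrics))
    return CentralityTable(network.labels, raw, z)


@dataclass
class SmallWorldResult:
    clustering: float
    avg_path_length: float
    c_random: float
    l_random: float
    index: float
    n_random: int

    @property
    def is_small_world(self) -> bool:
        """The conventional reading: an index above 1 marks a small world."""
        return bool(self.index > 1)

    def to_dict(self) -> dict:
        return {
            "clustering": self.clustering,
            "avg_path_length": self.avg_path_length,
            "c_random": self.c_random,
            "l_random": self.l_random,
            "index": self.index,
            "n_random": self.n_random,
        }


def _mean_path_length(g: nx.Graph) -> float:
    """Mean unweighted shortest-path length over connected node pairs."""
    total = 0.0
    pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
    if pairs == 0:
        return float("nan")
    return total / pairs


def small_world(
    network: IsingNetwork | nx.Graph, n_random: int = 1000, seed: int = 0
) -> SmallWorldResult:
    """Small-world index against edge-count-matched Erdos-Renyi references.

    Edges are binarized (any nonzero weight counts); C is the global
    transitivity, L the mean shortest path over connected pairs.
    """
    if isinstance(network, nx.Graph):
        g = nx.convert_node_labels_to_integers(network)
    else:
        g = _length_graph(network)
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    if n_edges == 0:
        raise ValueError("small_world needs a network with at least one edge")
    c_obs = nx.transitivity(g)
    l_obs = _mean_path_length(g)
    rng = np.random.default_rng(seed)
    c_rand = np.empty(n_random)
    l_rand = np.empty(n_random)
    for b in range(n_random):
        gr = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
        c_rand[b] = nx.transitivity(gr)
        l_rand[b] = _mean_path_length(gr)
    c_ref = float(np.mean(c_rand))
    l_ref = float(np.nanmean(l_rand))
    if c_ref == 0:
        warnings.warn(
            "random reference graphs have zero clustering; index undefined",
            stacklevel=2,
        )
        index = float("nan")
    else:
        index = (c_obs / c_ref) / (l_obs / l_ref)
    return SmallWorldResult(c_obs, l_obs, c_ref, l_ref, index, n_random)
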