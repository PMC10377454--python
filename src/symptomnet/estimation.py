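"""Regularized Ising network estimation from binary symptom data.

The estimator is the nodewise "eLASSO" procedure standard in psychometric
network analysis: for every symptom i, an L1-penalized logistic regression
of column i on all remaining columns is fit over a descending penalty path,
the per-node model is selected by the extended BIC

    EBIC = -2 loglik + k log n + 2 gamma k log(p - 1),

with k the number of nonzero neighbor coefficients, and the two directed
coefficient estimates for each pair are symmetrized (AND rule by default:
an edge exists only if both directions are selected, its weight the mean
of the two estimates). Node intercepts become the Ising thresholds.

Also here: the descriptive Pearson (phi) correlation matrix and a
Fruchterman-Reingold layout with attraction proportional to |w|.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logit

from ._kernels import logistic_lasso_path
from .datasets import SymptomDataset

_PACK_GUARD = 30  # columns; above this, aggregate rows without bit packing


@dataclass
class EstimatorConfig:
    """Settings for :func:`fit_ising`, shared by every stage that refits."""

    gamma: float = 0.25
    rule: str = "AND"
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01

    def __post_init__(self) -> None:
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations (= phi coefficient on 0/1 data)."""

    values: np.ndarray
    labels: list[str]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class IsingNetwork:
    """Estimated network: thresholds tau and sparse symmetric weights w."""

    labels: list[str]
    thresholds: np.ndarray
    weights: np.ndarray
    gamma: float | None = None
    rule: str | None = None

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("weight diagonal must be zero")

    @property
    def p(self) -> int:
        return len(self.labels)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0:
                    rows.append((self.labels[i], self.labels[j], self.weights[i, j]))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "labels": self.labels,
                    "thresholds": self.thresholds.tolist(),
                    "weights": self.weights.tolist(),
                    "gamma": self.gamma,
                    "rule": self.rule,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "IsingNetwork":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["labels"],
            np.array(d["thresholds"]),
            np.array(d["weights"]),
            d.get("gamma"),
            d.get("rule"),
        )

    def to_edgelist_tsv(self, path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False)

    def to_graph(self, absolute: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for _, row in self.edge_list().iterrows():
            w = abs(row.weight) if absolute else row.weight
            g.add_edge(row.node_i, row.node_j, weight=w)
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_graph(), path)


@dataclass
class LayoutCoordinates:
    labels: list[str]
    xy: np.ndarray


def pearson_matrix(data: SymptomDataset) -> CorrelationMatrix:
    """Pearson r between all symptom pairs; zero-variance columns give NaN."""
    x = data.values.astype(float)
    sd = x.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        bad = [data.labels[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(
            f"zero-variance symptom column(s) {bad}: correlations undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0, out=r)
    return CorrelationMatrix(r, data.labels)


def _aggregate_states(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse rows to (unique states, counts); key speedup for refits."""
    n, p = values.shape
    if p <= _PACK_GUARD:
        codes = values.astype(np.int64) @ (np.int64(1) << np.arange(p, dtype=np.int64))
        uniq, counts = np.unique(codes, return_counts=True)
        states = ((uniq[:, None] >> np.arange(p)) & 1).astype(np.float64)
    else:
        states, counts = np.unique(values, axis=0, return_counts=True)
        states = states.astype(np.float64)
    return states, counts.astype(np.float64)


def _fit_node(
    X: np.ndarray,
    y: np.ndarray,
    counts: np.ndarray,
    n: float,
    p: int,
    config: EstimatorConfig,
) -> tuple[float, np.ndarray]:
    """EBIC-selected L1 logistic fit of one node on its p-1 neighbors."""
    ybar = float((counts * y).sum() / n)
    if ybar in (0.0, 1.0):
        # degenerate response: no edges, clipped-frequency threshold
        freq = np.clip(ybar, 0.5 / n, 1 - 0.5 / n)
        return float(logit(freq)), np.zeros(X.shape[1])
    lam_max = np.max(np.abs((counts * (y - ybar)) @ X)) / n
    if lam_max <= 0:
        return float(logit(ybar)), np.zeros(X.shape[1])
    lambdas = np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambdas)
    # center predictors (glmnet-style): leaves the L1 slope solution
    # unchanged but decouples high-frequency columns from the intercept,
    # which is what makes coordinate descent converge quickly here
    mu = (counts @ X) / n
    XcT = np.ascontiguousarray((X - mu).T)
    intercepts, betas, logliks = logistic_lasso_path(
        XcT, y, counts, lambdas, 1e-6, 500
    )
    k = (betas != 0).sum(axis=1)
    ebic = -2.0 * logliks + k * np.log(n) + 2.0 * config.gamma * k * np.log(p - 1)
    best = int(np.argmin(ebic))  # lambdas descend: ties resolve to sparser
    return float(intercepts[best] - betas[best] @ mu), betas[best]


def _fit_from_states(
    states: np.ndarray,
    counts: np.ndarray,
    labels: list[str],
    config: EstimatorConfig,
) -> IsingNetwork:
    p = states.shape[1]
    n = float(counts.sum())
    others = np.arange(p)
    B = np.zeros((p, p))
    thresholds = np.zeros(p)
    for i in range(p):
        cols = others[others != i]
        intercept, beta = _fit_node(
            np.ascontiguousarray(states[:, cols]), states[:, i], counts, n, p, config
        )
        thresholds[i] = intercept
        B[i, cols] = beta
    nz = B != 0
    if config.rule == "AND":
        both = nz & nz.T
        W = np.where(both, (B + B.T) / 2.0, 0.0)
    else:  # OR: average over the nonzero directed estimates
        either = nz | nz.T
        denom = nz.astype(float) + nz.T.astype(float)
        with np.errstate(invalid="ignore"):
            W = np.where(either, (B + B.T) / np.where(denom == 0, 1.0, denom), 0.0)
    np.fill_diagonal(W, 0.0)
    return IsingNetwork(list(labels), thresholds, W, config.gamma, config.rule)


def fit_ising(
    data: SymptomDataset,
    gamma: float = 0.25,
    rule: str = "AND",
    config: EstimatorConfig | None = None,
) -> IsingNetwork:
    """Estimate the regularized Ising network by nodewise eLASSO.

    Parameters
    ----------
    data
        Binary symptom dataset.
    gamma
        EBIC sparsity hyperparameter (0.25 is the established default).
    rule
        ``"AND"`` (edge requires both directed selections) or ``"OR"``.
    config
        Full estimator configuration; overrides ``gamma``/``rule``.
    """
    cfg = config or EstimatorConfig(gamma=gamma, rule=rule)
    if data.n < 10 * data.p:
        warnings.warn(
            f"n={data.n} is below the recommended 10*p={10 * data.p}; "
            "estimates may be unstable",
            stacklevel=2,
        )
    sd = data.values.std(axis=0)
    if (sd == 0).any():
        bad = [data.labels[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(
            f"zero-variance symptom column(s) {bad}: node(s) retained with no edges",
            stacklevel=2,
        )
    states, counts = _aggregate_states(data.values)
    return _fit_from_states(states, counts, data.labels, cfg)


def fr_layout(
    network: IsingNetwork, seed: int = 0, iterations: int = 100
) -> LayoutCoordinates:
    """Fruchterman-Reingold coordinates; attraction scales with |w|."""
    pos = nx.spring_layout(
        network.to_graph(absolute=True), seed=seed, iterations=iterations
    )
    xy = np.array([pos[lab] for lab in network.labels])
    if not np.isfinite(xy).all():
        raise RuntimeError("layout produced non-finite coordinates")
    return LayoutCoordinates(network.labels, xy)
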