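"""Symptom frequencies and severity-adjusted group comparison.

Raw frequencies are simple column means per group. The adjusted
comparison fits, for each symptom, a multiple logistic regression of
symptom presence on a group indicator plus the participant's total
symptom count (the severity proxy), and reports the group odds ratio
with a 95% Wald confidence interval and two-sided p-value. By default
the modeled symptom is excluded from the adjustment count so the
covariate is not deterministically linked to the outcome.

Under perfect separation the maximum-likelihood odds ratio diverges; the
affected symptom is flagged and refit with Firth's bias-reduced
(Jeffreys-penalized) likelihood.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datasets import SymptomDataset


def symptom_frequencies(data: SymptomDataset) -> pd.Series:
    """Per-symptom frequency (column mean of the binary matrix)."""
    return pd.Series(data.values.mean(axis=0), index=data.labels, name=data.group)


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth bias-reduced logistic regression (Jeffreys prior penalty).

    Newton iteration on the modified score U*(b) = X'(y - p + h*(0.5 - p)),
    with h the hat-matrix diagonal. Returns (coef, cov).
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, XW)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    return beta, cov


def adjusted_comparison(
    data_a: SymptomDataset,
    data_b: SymptomDataset,
    exclude_symptom_from_count: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Severity-adjusted symptom-frequency comparison between two groups.

    For each symptom the model is

        logit P(symptom) = b0 + b1 * [group == b] + b2 * severity

    with severity the total symptom count (excluding the modeled symptom by
    default). The reported odds ratio exp(b1) is group b vs group a.

    Returns a table with per-group frequencies, OR, Wald CI and p-value,
    plus a ``separation`` flag for symptoms refit with Firth's penalty.
    """
    if data_a.labels != data_b.labels:
        raise ValueError("both datasets must share symptom labels and ordering")
    labels = data_a.labels
    x = np.vstack([data_a.values, data_b.values]).astype(float)
    group = np.r_[np.zeros(data_a.n), np.ones(data_b.n)]
    total = x.sum(axis=1)
    freq_a = symptom_frequencies(data_a)
    freq_b = symptom_frequencies(data_b)

    from scipy.stats import norm

    zcrit = norm.ppf(1 - alpha / 2)
    rows = []
    for j, lab in enumerate(labels):
        y = x[:, j]
        count = total - y if exclude_symptom_from_count else total
        X = np.column_stack([np.ones_like(y), group, count])
        if y.std() == 0 or count.std() == 0:
            warnings.warn(
                f"no variation for symptom {lab!r}; comparison undefined",
                stacklevel=2,
            )
            rows.append((lab, freq_a[lab], freq_b[lab], np.nan, np.nan, np.nan,
                         np.nan, False))
            continue
        separated = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                fit = sm.Logit(y, X).fit(method="newton", tol=1e-8, disp=0)
            b1 = fit.params[1]
            se = fit.bse[1]
            if not np.isfinite(se) or se > 100 or abs(b1) > 15:
                separated = True
        except Exception:
            separated = True
        if separated:
            warnings.warn(
                f"separation detected for symptom {lab!r}; "
                "Firth bias-reduced fit used",
                stacklevel=2,
            )
            beta, cov = _firth_logit(X, y)
            b1 = beta[1]
            se = float(np.sqrt(cov[1, 1]))
        z = b1 / se
        pval = 2 * norm.sf(abs(z))
        rows.append(
            (
                lab,
                freq_a[lab],
                freq_b[lab],
                np.exp(b1),
                np.exp(b1 - zcrit * se),
                np.exp(b1 + zcrit * se),
                pval,
                separated,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "symptom",
            "freq_a",
            "freq_b",
            "odds_ratio",
            "ci_low",
            "ci_high",
            "p_value",
            "separation",
        ],
    )
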