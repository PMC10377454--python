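"""Numba-compiled numerical cores.

Two hot loops live here: the single-site Gibbs sweep for sampling large
Ising models, and the L1-penalized logistic coordinate-descent path used
by the nodewise (eLASSO) network estimator. Both operate on plain float64
arrays so the surrounding modules stay testable without numba in the way.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_chain(thresholds, weights, n, burn_in, thin, u_init, u):  # pragma: no cover
    """Single-site Gibbs sampler for a {0,1} Ising model.

    ``u_init`` (length p) and ``u`` (total_sweeps x p) are pre-drawn
    uniforms so that determinism is owned by the caller's generator.
    """
    p = thresholds.shape[0]
    x = np.empty(p, dtype=np.float64)
    for i in range(p):
        x[i] = 1.0 if u_init[i] < 0.5 else 0.0
    out = np.empty((n, p), dtype=np.uint8)
    total = burn_in + (n - 1) * thin + 1
    t = 0
    for sweep in range(total):
        for i in range(p):
            eta = thresholds[i]
            for j in range(p):
                eta += weights[i, j] * x[j]
            prob = 1.0 / (1.0 + np.exp(-eta))
            x[i] = 1.0 if u[sweep, i] < prob else 0.0
        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            for i in range(p):
                out[t, i] = np.uint8(x[i])
            t += 1
    return out


@njit(cache=True, fastmath=True)
def logistic_lasso_path(XT, y, counts, lambdas, tol, max_sweeps):  # pragma: no cover
    """Coordinate descent over a descending L1 penalty path.

    Minimizes, for each penalty ``lam``,

        (1/N) * sum_s c_s * [log(1 + exp(eta_s)) - y_s * eta_s] + lam * ||beta||_1

    where columns of ``XT`` (d x m) are the distinct covariate patterns with
    multiplicities ``counts`` and N = sum(counts). The intercept is not
    penalized. The solver is penalized IRLS: an outer loop freezes the
    quadratic (working-response) approximation, an inner coordinate-descent
    loop with an active set solves the penalized weighted least squares;
    soft-thresholding yields exact zeros. Warm starts along the descending
    path; IRLS weights floored at 1e-5 against separation; the path stops
    early once the fit saturates (smaller penalties only chase separation
    and are never EBIC-optimal).

    Callers should center the rows of ``XT``: the slope solution is
    unchanged and coordinate descent converges far faster for
    high-frequency binary predictors.

    Returns (intercepts, betas, logliks): per-lambda intercept, coefficient
    vectors and the unpenalized total log-likelihood (summed over the N
    observations, not divided by N).
    """
    d, m = XT.shape
    n_lam = lambdas.shape[0]
    N = counts.sum()

    beta = np.zeros(d)
    b0 = 0.0
    eta = np.zeros(m)
    w = np.empty(m)  # IRLS weights, c * p * (1-p) / N
    q = np.empty(m)  # working residual, w * (z - eta)
    h = np.empty(d)  # per-coordinate curvature under the frozen weights
    active = np.zeros(d, dtype=np.uint8)
    intercepts = np.empty(n_lam)
    betas = np.zeros((n_lam, d))
    logliks = np.empty(n_lam)
    w_floor = 1e-5
    # null log-likelihood, for the saturation early-stop of the path
    ybar = 0.0
    for s in range(m):
        ybar += counts[s] * y[s]
    ybar /= N
    if ybar <= 0.0 or ybar >= 1.0:
        ll_null = 0.0
    else:
        ll_null = N * (ybar * np.log(ybar) + (1.0 - ybar) * np.log(1.0 - ybar))
    stopped_at = n_lam
    max_outer = 30

    for k in range(n_lam):
        lam = lambdas[k]
        for _outer in range(max_outer):
            # freeze the quadratic approximation at the current eta
            wsum = 0.0
            for s in range(m):
                prob = 1.0 / (1.0 + np.exp(-eta[s]))
                pw = prob * (1.0 - prob)
                if pw < w_floor:
                    pw = w_floor
                w[s] = counts[s] * pw / N
                wsum += w[s]
                q[s] = counts[s] * (y[s] - prob) / N
            # curvatures are fixed within this outer iteration
            for j in range(d):
                hj = 0.0
                for s in range(m):
                    hj += w[s] * XT[j, s] * XT[j, s]
                h[j] = hj
            outer_delta = 0.0
            for j in range(d):
                active[j] = 1 if beta[j] != 0.0 else 0
            force_full = False
            for _inner in range(max_sweeps):
                full_sweep = _inner == 0 or force_full
                delta_max = 0.0
                qsum = 0.0
                for s in range(m):
                    qsum += q[s]
                step0 = qsum / wsum
                if np.abs(step0) > delta_max:
                    delta_max = np.abs(step0)
                b0 += step0
                for s in range(m):
                    q[s] -= w[s] * step0
                    eta[s] += step0
                for j in range(d):
                    if not full_sweep and active[j] == 0:
                        continue
                    if h[j] < 1e-12:
                        continue
                    gj = 0.0
                    for s in range(m):
                        gj += XT[j, s] * q[s]
                    z = h[j] * beta[j] + gj
                    if z > lam:
                        new = (z - lam) / h[j]
                    elif z < -lam:
                        new = (z + lam) / h[j]
                    else:
                        new = 0.0
                    diff = new - beta[j]
                    if np.abs(diff) > delta_max:
                        delta_max = np.abs(diff)
                    if diff != 0.0:
                        beta[j] = new
                        if new != 0.0:
                            active[j] = 1
                        for s in range(m):
                            q[s] -= w[s] * XT[j, s] * diff
                            eta[s] += XT[j, s] * diff
                if np.abs(delta_max) > outer_delta:
                    outer_delta = delta_max
                if delta_max < tol:
                    if full_sweep:
                        break
                    force_full = True  # verify convergence with a full sweep
                else:
                    force_full = False
            if outer_delta < 10.0 * tol:
                break
        intercepts[k] = b0
        for j in range(d):
            betas[k, j] = beta[j]
        ll = 0.0
        for s in range(m):
            # log(1+exp(eta)) computed stably
            e = eta[s]
            if e > 30.0:
                lse = e
            elif e < -30.0:
                lse = 0.0
            else:
                lse = np.log(1.0 + np.exp(e))
            ll += counts[s] * (y[s] * e - lse)
        logliks[k] = ll
        # early stop once the fit is essentially saturated; smaller lambdas
        # only chase separation and are never EBIC-optimal
        if ll_null < 0.0 and ll > 0.001 * ll_null:
            stopped_at = k + 1
            break
    for k in range(stopped_at, n_lam):
        intercepts[k] = intercepts[stopped_at - 1]
        for j in range(d):
            betas[k, j] = betas[stopped_at - 1, j]
        logliks[k] = logliks[stopped_at - 1]
    return intercepts, betas, logliks
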