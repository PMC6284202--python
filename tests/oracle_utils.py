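"""Independent oracles used only by the test suite.

These deliberately avoid the package's vectorized code paths: the mixture
log-likelihood is evaluated by explicit Python loops over classes and items,
and the two-class maximum is located by dense grid search over the raw
probability parameters followed by a local polish of the likelihood itself
(direct numerical maximization, not EM).
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit


def brute_loglik(responses, weights, proportions, response_probs) -> float:
    """Mixture log-likelihood by explicit enumeration of every class term."""
    total = 0.0
    for i, row in enumerate(responses):
        p_case = 0.0
        for k, pi_k in enumerate(proportions):
            term = pi_k
            for j, code in enumerate(row):
                term *= response_probs[j][k][code - 1]
            p_case += term
        if weights[i] > 0:
            total += weights[i] * np.log(p_case)
    return total


def brute_ranking_loglik(first, second, weights, proportions, logits) -> float:
    """Top-2 mixture log-likelihood by explicit enumeration."""
    total = 0.0
    for i in range(first.shape[0]):
        p_case = 0.0
        for k, pi_k in enumerate(proportions):
            term = pi_k
            for j in range(first.shape[1]):
                tau = np.exp(logits[j][k])
                s = tau.sum()
                a1, a2 = first[i, j], second[i, j]
                term *= tau[a1 - 1] / s * tau[a2 - 1] / (s - tau[a1 - 1])
            p_case += term
        if weights[i] > 0:
            total += weights[i] * np.log(p_case)
    return total


def _loglik_binary_2class(x, responses, weights):
    """x = (pi_1, theta_{1,1..J}, theta_{2,1..J}) for binary items, K=2."""
    j = responses.shape[1]
    pi1 = x[0]
    t1, t2 = x[1:1 + j], x[1 + j:]
    is1 = responses == 1
    f1 = np.prod(np.where(is1, t1, 1 - t1), axis=1)
    f2 = np.prod(np.where(is1, t2, 1 - t2), axis=1)
    p = pi1 * f1 + (1 - pi1) * f2
    keep = weights > 0
    with np.errstate(divide="ignore"):
        return float(np.sum(weights[keep] * np.log(p[keep])))


def grid_best_loglik_2class(responses, weights, coarse: int = 21) -> float:
    """Best two-class log-likelihood for binary items by grid + polish.

    Dense grid over (pi, theta) for J <= 2 binary items (a 2J+1 dimensional
    search), refined twice around the incumbent, then polished by direct
    quasi-Newton maximization of the likelihood on the logit scale.
    """
    responses = np.asarray(responses)
    weights = np.asarray(weights, dtype=float)
    j = responses.shape[1]
    assert j <= 2, "grid oracle supports at most 2 items"

    def evaluate(grids):
        mesh = np.meshgrid(*grids, indexing="ij")
        flat = np.stack([m.ravel() for m in mesh], axis=1)
        best_val, best_x = -np.inf, None
        # chunk to bound memory
        for start in range(0, flat.shape[0], 200_000):
            chunk = flat[start:start + 200_000]
            pi1 = chunk[:, 0:1]
            t1 = chunk[:, 1:1 + j]
            t2 = chunk[:, 1 + j:]
            is1 = responses == 1  # (N, J)
            f1 = np.prod(np.where(is1[None], t1[:, None, :], 1 - t1[:, None, :]), axis=2)
            f2 = np.prod(np.where(is1[None], t2[:, None, :], 1 - t2[:, None, :]), axis=2)
            p = pi1 * f1 + (1 - pi1) * f2
            keep = weights > 0
            ll = (weights[keep][None] * np.log(p[:, keep])).sum(axis=1)
            q = int(np.argmax(ll))
            if ll[q] > best_val:
                best_val, best_x = float(ll[q]), chunk[q]
        return best_val, best_x

    lo, hi = 1e-6, 1 - 1e-6
    grids = [np.linspace(0.05, 0.95, coarse)] + \
            [np.linspace(0.02, 0.98, coarse)] * (2 * j)
    val, x = evaluate(grids)
    step = 0.05
    for _ in range(2):
        grids = [np.clip(np.linspace(c - step, c + step, 21), lo, hi) for c in x]
        val, x = evaluate(grids)
        step /= 10

    # final polish: direct likelihood maximization on the logit scale
    def neg(z):
        return -_loglik_binary_2class(expit(z), responses, weights)

    res = minimize(neg, logit(np.clip(x, lo, hi)), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return max(val, -res.fun)
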