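"""Weighted maximum-likelihood estimation of latent class models.

A K-class latent class (LC) model for J categorical indicators is the finite
mixture

    P(y_i) = sum_k pi_k * prod_j theta_{jk}(y_ij),

with class proportions ``pi`` and class-conditional response probabilities
``theta`` (local independence within class). Estimation maximizes the weighted
log-likelihood ``sum_i w_i log P(y_i)`` by EM, where the case weights ``w_i``
are 1 for an ordinary analysis and posterior node-membership probabilities
when a model is fitted at an interior node of a latent class tree.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .data import CategoricalDataset

__all__ = [
    "LCParameters",
    "FitResult",
    "ZeroProbabilityError",
    "weighted_loglik",
    "posterior",
    "em_fit",
    "n_parameters",
    "information_criteria",
    "IndicatorModel",
]


class ZeroProbabilityError(ArithmeticError):
    """A case receives probability zero under the model being evaluated."""


@dataclass(frozen=True)
class LCParameters:
    """Parameters of a K-class model for categorical indicators.

    ``proportions`` is the length-K class-proportion vector; ``response_probs``
    holds, per item j, a ``(K, C_j)`` matrix whose rows are the conditional
    category distributions for each class.
    """

    n_classes: int
    proportions: np.ndarray
    response_probs: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        pi = np.asarray(self.proportions, dtype=float)
        if pi.shape != (self.n_classes,):
            raise ValueError("proportions must have length n_classes")
        if (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-6:
            raise ValueError("proportions must be in (0, 1] and sum to 1")
        probs = tuple(np.asarray(p, dtype=float) for p in self.response_probs)
        for j, p in enumerate(probs):
            if p.ndim != 2 or p.shape[0] != self.n_classes or p.shape[1] < 2:
                raise ValueError(f"response_probs[{j}] must be (K, C_j) with C_j >= 2")
            if (p < 0).any() or (p > 1).any():
                raise ValueError(f"response_probs[{j}] entries must lie in [0, 1]")
            if np.abs(p.sum(axis=1) - 1.0).max() > 1e-6:
                raise ValueError(f"response_probs[{j}] rows must sum to 1")
        object.__setattr__(self, "proportions", pi)
        object.__setattr__(self, "response_probs", probs)

    @property
    def n_categories(self) -> np.ndarray:
        return np.array([p.shape[1] for p in self.response_probs])

    def permuted(self, order: Sequence[int]) -> "LCParameters":
        """Relabel classes according to ``order`` (a permutation of 0..K-1)."""
        order = list(order)
        return replace(
            self,
            proportions=self.proportions[order],
            response_probs=tuple(p[order] for p in self.response_probs),
        )


@dataclass(frozen=True)
class FitResult:
    """A converged (or flagged) maximum-likelihood solution."""

    params: object
    loglik: float
    n_params: int
    n_cases_effective: float
    n_total: int
    bic: float
    aic: float
    posteriors: np.ndarray
    converged: bool
    n_iterations: int
    n_starts_used: int
    seed: int | None
    loglik_trace: tuple[float, ...] = field(default=(), repr=False)

    @property
    def n_classes(self) -> int:
        return self.params.n_classes


def _check_dims(data: CategoricalDataset, params: LCParameters) -> None:
    if len(params.response_probs) != data.n_items:
        raise ValueError("params cover a different number of items than the data")
    for j, p in enumerate(params.response_probs):
        if p.shape[1] < data.n_categories[j]:
            raise ValueError(
                f"params for item {data.item_labels[j]!r} have {p.shape[1]} "
                f"categories but the data declare {data.n_categories[j]}"
            )


def _log_components(responses: np.ndarray, params: LCParameters) -> np.ndarray:
    """(N, K) matrix of log( pi_k * prod_j theta_jk(y_ij) )."""
    n = responses.shape[0]
    with np.errstate(divide="ignore"):
        comp = np.broadcast_to(np.log(params.proportions), (n, params.n_classes)).copy()
        for j, probs in enumerate(params.response_probs):
            comp += np.log(probs[:, responses[:, j] - 1]).T
    return comp


def weighted_loglik(data: CategoricalDataset, params: LCParameters) -> float:
    """Weighted log-likelihood ``sum_i w_i log sum_k pi_k prod_j theta``.

    Cases with zero weight contribute nothing (and may have zero model
    probability); a case with positive weight and zero probability raises
    :class:`ZeroProbabilityError`.
    """
    _check_dims(data, params)
    comp = _log_components(data.responses, params)
    lse = logsumexp(comp, axis=1)
    pos = data.weights > 0
    if np.isneginf(lse[pos]).any():
        i = int(np.nonzero(pos & np.isneginf(lse))[0][0])
        raise ZeroProbabilityError(
            f"case {i} has positive weight but probability zero under the model"
        )
    return float(np.sum(data.weights[pos] * lse[pos]))


def posterior(data: CategoricalDataset, params: LCParameters) -> np.ndarray:
    """Posterior class-membership probabilities, one row per case.

    Row i is ``pi_k prod_j theta_jk(y_ij)`` normalized over classes (Bayes
    rule); rows sum to 1. A case whose total probability is zero raises
    :class:`ZeroProbabilityError`.
    """
    _check_dims(data, params)
    comp = _log_components(data.responses, params)
    lse = logsumexp(comp, axis=1)
    if np.isneginf(lse).any():
        i = int(np.nonzero(np.isneginf(lse))[0][0])
        raise ZeroProbabilityError(
            f"case {i} has probability zero under every class"
        )
    return np.exp(comp - lse[:, None])


def n_parameters(K: int, n_categories: Sequence[int]) -> int:
    """Free-parameter count ``(K - 1) + K * sum_j (C_j - 1)``."""
    if K < 1:
        raise ValueError("K must be >= 1")
    ncat = np.asarray(n_categories, dtype=np.int64)
    return int((K - 1) + K * (ncat - 1).sum())


def information_criteria(loglik: float, n_params: int, n: float) -> dict:
    """BIC ``-2 logL + log(n) P`` and AIC ``-2 logL + 2 P``."""
    if n <= 0:
        raise ValueError("n must be positive")
    return {
        "bic": float(-2.0 * loglik + np.log(n) * n_params),
        "aic": float(-2.0 * loglik + 2.0 * n_params),
    }


def _m_step(
    responses: np.ndarray,
    weights: np.ndarray,
    post: np.ndarray,
    n_categories: np.ndarray,
    prob_floor: float,
) -> LCParameters:
    wp = weights[:, None] * post                      # (N, K)
    class_mass = wp.sum(axis=0)
    class_mass = np.maximum(class_mass, 1e-300)
    pi = class_mass / class_mass.sum()
    pi = np.maximum(pi, 1e-12)
    pi = pi / pi.sum()
    probs = []
    for j, cj in enumerate(n_categories):
        counts = np.empty((post.shape[1], cj))
        codes = responses[:, j] - 1
        for c in range(cj):
            counts[:, c] = wp[codes == c].sum(axis=0)
        theta = counts / class_mass[:, None]
        theta = np.maximum(theta, prob_floor)
        theta /= theta.sum(axis=1, keepdims=True)
        probs.append(theta)
    return LCParameters(post.shape[1], pi, tuple(probs))


def _one_class_fit(
    data: CategoricalDataset,
    weights: np.ndarray,
    prob_floor: float,
    ic_n: float,
    seed: int | None,
) -> FitResult:
    n = data.n_cases
    post = np.ones((n, 1))
    params = _m_step(data.responses, weights, post, data.n_categories, prob_floor)
    ll = weighted_loglik(data.with_weights(weights), params)
    p = n_parameters(1, data.n_categories)
    ic = information_criteria(ll, p, ic_n)
    return FitResult(
        params=params, loglik=ll, n_params=p,
        n_cases_effective=float(weights.sum()), n_total=n,
        bic=ic["bic"], aic=ic["aic"], posteriors=post,
        converged=True, n_iterations=0, n_starts_used=1, seed=seed,
        loglik_trace=(ll,),
    )


def em_fit(
    data: CategoricalDataset,
    K: int,
    *,
    n_starts: int = 16,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int | None = None,
    prob_floor: float = 1e-6,
    weights: np.ndarray | None = None,
    ic_sample_size: float | None = None,
) -> FitResult:
    """Fit a K-class model by EM, keeping the best of ``n_starts`` starts.

    Each start draws random soft class assignments, applies the closed-form
    weighted M-step, and alternates E and M steps until the relative change in
    weighted log-likelihood falls below ``tol`` or ``max_iter`` is reached.
    Response probabilities are floored at ``prob_floor`` (and renormalized) to
    keep every observed pattern at positive probability.

    ``ic_sample_size`` is the n entered in the BIC penalty; it defaults to the
    number of rows N (the root sample size), which is also the convention used
    at interior tree nodes unless a node-size penalty is requested.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    w = data.weights if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (data.n_cases,):
        raise ValueError("weights must be length N")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("sum of weights must be positive")
    ic_n = float(data.n_cases) if ic_sample_size is None else float(ic_sample_size)
    if K == 1:
        return _one_class_fit(data, w, prob_floor, ic_n, seed)

    # Collapse to unique response patterns with aggregated weights: the
    # likelihood, M-step, and per-pattern posteriors are identical, so this
    # is an exact reformulation, not an approximation.
    resp_u, inverse = np.unique(data.responses, axis=0, return_inverse=True)
    w_u = np.bincount(inverse, weights=w, minlength=resp_u.shape[0])
    n_patterns = int((w_u > 0).sum())
    if K > n_patterns:
        warnings.warn(
            f"K={K} exceeds the {n_patterns} distinct observed patterns; "
            "boundary solutions are likely",
            stacklevel=2,
        )

    master = np.random.SeedSequence(seed)
    best = None
    for child in master.spawn(n_starts):
        rng = np.random.default_rng(child)
        post = rng.dirichlet(np.ones(K), size=resp_u.shape[0])
        prev = -np.inf
        trace = []
        converged = False
        params = None
        for it in range(1, max_iter + 1):
            params = _m_step(resp_u, w_u, post, data.n_categories, prob_floor)
            comp = _log_components(resp_u, params)
            lse = logsumexp(comp, axis=1)
            ll = float(np.sum(np.where(w_u > 0, w_u * lse, 0.0)))
            post = np.exp(comp - lse[:, None])
            trace.append(ll)
            if np.isfinite(prev) and ll < prev - 1e-8 * (abs(prev) + 1.0):
                warnings.warn("EM log-likelihood decreased; numerical trouble",
                              stacklevel=2)
            if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1.0):
                converged = True
                break
            prev = ll
        if not converged:
            warnings.warn(
                f"EM did not converge within {max_iter} iterations (K={K})",
                stacklevel=2,
            )
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], params, post, converged, len(trace), tuple(trace))

    ll, params, post, converged, n_iter, trace = best
    post = post[inverse]  # expand pattern posteriors back to all N cases
    p = n_parameters(K, data.n_categories)
    ic = information_criteria(ll, p, ic_n)
    return FitResult(
        params=params, loglik=ll, n_params=p,
        n_cases_effective=float(w.sum()), n_total=data.n_cases,
        bic=ic["bic"], aic=ic["aic"], posteriors=post,
        converged=converged, n_iterations=n_iter, n_starts_used=n_starts,
        seed=seed, loglik_trace=trace,
    )


class IndicatorModel:
    """Adapter exposing the categorical-indicator LC model to generic callers.

    The tree builder and the fit-table machinery only need ``fit`` and
    ``n_parameters``; this thin wrapper lets the same code drive the ranking
    (discrete choice) likelihood through an identical surface.
    """

    def __init__(self, **defaults):
        self.defaults = defaults

    def fit(self, data: CategoricalDataset, K: int, *, weights=None,
            seed=None, ic_sample_size=None, **options) -> FitResult:
        opts = {**self.defaults, **options}
        return em_fit(data, K, weights=weights, seed=seed,
                      ic_sample_size=ic_sample_size, **opts)

    def n_parameters(self, data: CategoricalDataset, K: int) -> int:
        return n_parameters(K, data.n_categories)
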