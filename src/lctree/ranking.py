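"""Latent class discrete-choice model for top-2 (first/second choice) items.

Each item presents A_j alternatives; a respondent names a first and a second
choice. Within class k, alternative a of item j carries a utility
``tau_jak = exp(beta_jak)`` and the probability of the ordered pair (a1, a2)
is the two-stage (Plackett-Luce-style) product

    P(a1, a2 | k) = tau_a1 / sum_a tau_a  *  tau_a2 / sum_{a != a1} tau_a,

i.e. the second choice is drawn from the non-selected alternatives with the
same utilities as the first. The logits are effects-coded (they sum to zero
over alternatives within each item and class), giving A_j - 1 free logits per
item per class and K - 1 free class proportions. Items are locally
independent given class. Estimation is weighted EM with an inner quasi-Newton
maximization of the free logits per class and item; the inner problem depends
on the data only through the weighted count of each ordered pair, and it is
concave, so the M-step is exact to the inner tolerance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .lc import FitResult, ZeroProbabilityError, information_criteria

__all__ = [
    "RankingDataset",
    "RankingParameters",
    "pair_prob",
    "pair_prob_table",
    "ranking_loglik",
    "ranking_posterior",
    "fit_ranking_lc",
    "n_parameters_ranking",
    "RankingModel",
]


@dataclass(frozen=True)
class RankingDataset:
    """First and second choices per case and item, with case weights."""

    first: np.ndarray           # (N, J), codes 1..A_j
    second: np.ndarray          # (N, J), codes 1..A_j, != first
    weights: np.ndarray
    n_alternatives: np.ndarray  # (J,)
    item_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a1 = np.asarray(self.first, dtype=np.int64)
        a2 = np.asarray(self.second, dtype=np.int64)
        if a1.ndim != 2 or a1.shape != a2.shape or a1.shape[0] < 1:
            raise ValueError("first and second must be matching (N, J) arrays")
        nalt = np.asarray(self.n_alternatives, dtype=np.int64)
        if nalt.shape != (a1.shape[1],) or (nalt < 2).any():
            raise ValueError("n_alternatives must be length J with A_j >= 2")
        for arr, name in ((a1, "first"), (a2, "second")):
            if (arr < 1).any() or (arr > nalt[None, :]).any():
                raise ValueError(f"{name} choices must be codes in 1..A_j")
        if (a1 == a2).any():
            i, j = np.argwhere(a1 == a2)[0]
            raise ValueError(
                f"first and second choice coincide at row {i}, item "
                f"{self.item_labels[j]!r}"
            )
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (a1.shape[0],) or (w < 0).any() or not (w > 0).any():
            raise ValueError("weights must be nonnegative, length N, not all zero")
        if len(self.item_labels) != a1.shape[1]:
            raise ValueError("item_labels must have one entry per item")
        object.__setattr__(self, "first", a1)
        object.__setattr__(self, "second", a2)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "n_alternatives", nalt)
        object.__setattr__(self, "item_labels", tuple(self.item_labels))

    @classmethod
    def from_arrays(cls, first, second, weights=None, item_labels=None,
                    n_alternatives=None) -> "RankingDataset":
        a1 = np.asarray(first)
        a2 = np.asarray(second)
        n, j = a1.shape
        if weights is None:
            weights = np.ones(n)
        if item_labels is None:
            item_labels = tuple(f"item{q + 1}" for q in range(j))
        if n_alternatives is None:
            n_alternatives = np.maximum(np.maximum(a1.max(0), a2.max(0)), 2)
        return cls(a1, a2, np.asarray(weights, dtype=float),
                   np.asarray(n_alternatives), tuple(item_labels))

    @property
    def n_cases(self) -> int:
        return self.first.shape[0]

    @property
    def n_items(self) -> int:
        return self.first.shape[1]

    def with_weights(self, weights) -> "RankingDataset":
        import dataclasses
        return dataclasses.replace(self, weights=np.asarray(weights, dtype=float))


@dataclass(frozen=True)
class RankingParameters:
    """Class proportions and effects-coded class-specific logits.

    ``logits[j]`` is ``(K, A_j)`` with each row summing to zero; utilities are
    ``exp(logits)``.
    """

    n_classes: int
    proportions: np.ndarray
    logits: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        pi = np.asarray(self.proportions, dtype=float)
        if pi.shape != (self.n_classes,) or (pi <= 0).any() or abs(pi.sum() - 1) > 1e-6:
            raise ValueError("proportions must be positive and sum to 1")
        logits = tuple(np.asarray(b, dtype=float) for b in self.logits)
        for j, b in enumerate(logits):
            if b.ndim != 2 or b.shape[0] != self.n_classes or b.shape[1] < 2:
                raise ValueError(f"logits[{j}] must be (K, A_j)")
            if np.abs(b.sum(axis=1)).max() > 1e-8:
                raise ValueError(
                    f"logits[{j}] rows must sum to 0 (effects coding)"
                )
        object.__setattr__(self, "proportions", pi)
        object.__setattr__(self, "logits", logits)

    @property
    def utilities(self) -> tuple[np.ndarray, ...]:
        return tuple(np.exp(b) for b in self.logits)

    @property
    def n_alternatives(self) -> np.ndarray:
        return np.array([b.shape[1] for b in self.logits])


def pair_prob(beta, a1: int, a2: int) -> float:
    """Probability of first choice ``a1`` then second choice ``a2`` (1-based).

    Invariant to adding a constant to all logits of the item-class.
    """
    if a1 == a2:
        raise ValueError("first and second choice must differ")
    beta = np.asarray(beta, dtype=float)
    if not (1 <= a1 <= beta.size and 1 <= a2 <= beta.size):
        raise ValueError("choices must index the alternatives 1..A")
    tau = np.exp(beta - beta.max())
    s = tau.sum()
    return float(tau[a1 - 1] / s * tau[a2 - 1] / (s - tau[a1 - 1]))


def pair_prob_table(beta) -> np.ndarray:
    """(A, A) table of ordered-pair probabilities; the diagonal is zero."""
    beta = np.asarray(beta, dtype=float)
    tau = np.exp(beta - beta.max())
    s = tau.sum()
    t = (tau[:, None] / s) * (tau[None, :] / (s - tau[:, None]))
    np.fill_diagonal(t, 0.0)
    return t


def _log_components(data: RankingDataset, params: RankingParameters) -> np.ndarray:
    if len(params.logits) != data.n_items:
        raise ValueError("params cover a different number of items than the data")
    n, k = data.n_cases, params.n_classes
    with np.errstate(divide="ignore"):
        comp = np.broadcast_to(np.log(params.proportions), (n, k)).copy()
        for j, b in enumerate(params.logits):
            if b.shape[1] < data.n_alternatives[j]:
                raise ValueError(
                    f"params for item {data.item_labels[j]!r} cover fewer "
                    "alternatives than the data"
                )
            tables = np.stack([pair_prob_table(b[q]) for q in range(k)])  # (K, A, A)
            comp += np.log(tables[:, data.first[:, j] - 1, data.second[:, j] - 1]).T
    return comp


def ranking_loglik(data: RankingDataset, params: RankingParameters) -> float:
    """Weighted mixture log-likelihood of the top-2 choice data."""
    comp = _log_components(data, params)
    lse = logsumexp(comp, axis=1)
    pos = data.weights > 0
    if np.isneginf(lse[pos]).any():
        i = int(np.nonzero(pos & np.isneginf(lse))[0][0])
        raise ZeroProbabilityError(
            f"case {i} has positive weight but probability zero under the model"
        )
    return float(np.sum(data.weights[pos] * lse[pos]))


def ranking_posterior(data: RankingDataset, params: RankingParameters) -> np.ndarray:
    """Posterior class-membership probabilities; rows sum to 1."""
    comp = _log_components(data, params)
    lse = logsumexp(comp, axis=1)
    if np.isneginf(lse).any():
        i = int(np.nonzero(np.isneginf(lse))[0][0])
        raise ZeroProbabilityError(f"case {i} has probability zero under every class")
    return np.exp(comp - lse[:, None])


def n_parameters_ranking(K: int, n_alternatives) -> int:
    """Free-parameter count ``(K - 1) + K * sum_j (A_j - 1)``."""
    if K < 1:
        raise ValueError("K must be >= 1")
    nalt = np.asarray(n_alternatives, dtype=np.int64)
    return int((K - 1) + K * (nalt - 1).sum())


def _beta_from_free(z: np.ndarray) -> np.ndarray:
    return np.append(z, -z.sum())


def _fit_item_class(counts: np.ndarray, z0: np.ndarray, inner_tol: float) -> np.ndarray:
    """Maximize the weighted pair log-likelihood for one item and class.

    ``counts[a1, a2]`` is the posterior-weighted count of the ordered pair.
    The objective (normalized by the total count) is concave in the logits;
    BFGS with the analytic gradient solves the free, effects-coded
    parameterization.
    """
    tot = counts.sum()
    if tot <= 0:
        return z0
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)

    def negloglik(z):
        beta = _beta_from_free(z)
        shift = beta.max()
        tau = np.exp(beta - shift)
        s = tau.sum()
        rest = s - tau
        ll = ((row + col) @ (beta - shift)
              - tot * np.log(s) - row @ np.log(rest))
        q = (row / rest).sum()
        grad_b = (row + col) - tot * tau / s - tau * (q - row / rest)
        grad_z = grad_b[:-1] - grad_b[-1]
        return -ll / tot, -grad_z / tot

    res = minimize(negloglik, z0, jac=True, method="BFGS",
                   options={"gtol": inner_tol, "maxiter": 500})
    z = res.x
    beta = _beta_from_free(z)
    return beta[:-1] - beta.mean()  # recentre exactly (effects coding)


def _m_step_ranking(data, weights, post, free_logits, inner_tol):
    wp = weights[:, None] * post
    class_mass = np.maximum(wp.sum(axis=0), 1e-300)
    pi = np.maximum(class_mass / class_mass.sum(), 1e-12)
    pi = pi / pi.sum()
    K = post.shape[1]
    for j in range(data.n_items):
        a = data.n_alternatives[j]
        for q in range(K):
            counts = np.zeros((a, a))
            np.add.at(counts, (data.first[:, j] - 1, data.second[:, j] - 1), wp[:, q])
            free_logits[j][q] = _fit_item_class(counts, free_logits[j][q], inner_tol)
    logits = tuple(
        np.stack([_beta_from_free(free_logits[j][q]) for q in range(K)])
        for j in range(data.n_items)
    )
    return RankingParameters(K, pi, logits)


def fit_ranking_lc(
    data: RankingDataset,
    K: int,
    *,
    n_starts: int = 16,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed: int | None = None,
    inner_tol: float = 1e-9,
    weights: np.ndarray | None = None,
    ic_sample_size: float | None = None,
) -> FitResult:
    """Fit the K-class top-2 discrete-choice model by EM with multiple starts.

    The effects-coding constraint is built into the parameterization (A_j - 1
    free logits per item and class), so it holds exactly at every step.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    w = data.weights if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (data.n_cases,):
        raise ValueError("weights must be length N")
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    ic_n = float(data.n_cases) if ic_sample_size is None else float(ic_sample_size)
    wdata = data.with_weights(w)

    def fresh_logits():
        return [
            [np.zeros(data.n_alternatives[j] - 1) for _ in range(K)]
            for j in range(data.n_items)
        ]

    if K == 1:
        # single M-step from the trivial posterior solves the concave MLE
        post = np.ones((data.n_cases, 1))
        params = _m_step_ranking(data, w, post, fresh_logits(), inner_tol)
        ll = ranking_loglik(wdata, params)
        p = n_parameters_ranking(1, data.n_alternatives)
        ic = information_criteria(ll, p, ic_n)
        return FitResult(params=params, loglik=ll, n_params=p,
                         n_cases_effective=float(w.sum()), n_total=data.n_cases,
                         bic=ic["bic"], aic=ic["aic"], posteriors=post,
                         converged=True, n_iterations=1, n_starts_used=1,
                         seed=seed, loglik_trace=(ll,))

    # collapse to unique (first, second) patterns — exact, see lc.em_fit
    key = np.column_stack([data.first, data.second])
    key_u, inverse = np.unique(key, axis=0, return_inverse=True)
    w_u = np.bincount(inverse, weights=w, minlength=key_u.shape[0])
    j = data.n_items
    cdata = RankingDataset(key_u[:, :j], key_u[:, j:], np.ones(key_u.shape[0]),
                           data.n_alternatives, data.item_labels)

    master = np.random.SeedSequence(seed)
    best = None
    for child in master.spawn(n_starts):
        rng = np.random.default_rng(child)
        post = rng.dirichlet(np.ones(K), size=cdata.n_cases)
        free = fresh_logits()
        prev = -np.inf
        trace: list[float] = []
        converged = False
        params = None
        for _ in range(1, max_iter + 1):
            params = _m_step_ranking(cdata, w_u, post, free, inner_tol)
            comp = _log_components(cdata, params)
            lse = logsumexp(comp, axis=1)
            ll = float(np.sum(np.where(w_u > 0, w_u * lse, 0.0)))
            post = np.exp(comp - lse[:, None])
            trace.append(ll)
            if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1.0):
                converged = True
                break
            prev = ll
        if not converged:
            warnings.warn(
                f"ranking EM did not converge within {max_iter} iterations (K={K})",
                stacklevel=2,
            )
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], params, post, converged, len(trace), tuple(trace))

    ll, params, post, converged, n_iter, trace = best
    post = post[inverse]  # expand pattern posteriors back to all N cases
    p = n_parameters_ranking(K, data.n_alternatives)
    ic = information_criteria(ll, p, ic_n)
    return FitResult(params=params, loglik=ll, n_params=p,
                     n_cases_effective=float(w.sum()), n_total=data.n_cases,
                     bic=ic["bic"], aic=ic["aic"], posteriors=post,
                     converged=converged, n_iterations=n_iter,
                     n_starts_used=n_starts, seed=seed, loglik_trace=trace)


class RankingModel:
    """Adapter plugging the discrete-choice likelihood into the tree builder."""

    def __init__(self, **defaults):
        self.defaults = defaults

    def fit(self, data: RankingDataset, K: int, *, weights=None, seed=None,
            ic_sample_size=None, **options) -> FitResult:
        opts = {**self.defaults, **options}
        return fit_ranking_lc(data, K, weights=weights, seed=seed,
                              ic_sample_size=ic_sample_size, **opts)

    def n_parameters(self, data: RankingDataset, K: int) -> int:
        return n_parameters_ranking(K, data.n_alternatives)
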