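"""Synthetic-data generators and the relative-improvement simulation study.

Three built-in class configurations (A, B, C) for 10 binary items with equal
class sizes probe when a binary root split is adequate:

* **A** — three classes: one distinct class with high response probabilities
  on every item, plus two fairly similar classes whose item probabilities
  average 0.2 and differ only moderately on a few items. Binary splits work:
  the root separates the distinct class, the next split resolves the pair.
* **B** — three mutually well-separated classes. A binary root smears the
  third class over both children, so a ternary root is called for.
* **C** — four classes forming two macro-clusters: classes 1-2 average a
  response probability of 0.8 and classes 3-4 average 0.2, with moderate
  within-pair differences on disjoint item subsets. A binary root separates
  the macro-clusters and two further binary splits recover all four classes.

Exact generating probabilities are documented constants chosen to satisfy
those qualitative descriptions; see ``CONFIG_PROFILES``.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import CategoricalDataset
from .ranking import RankingDataset, RankingParameters, pair_prob_table
from .selection import fit_table, relative_improvement

__all__ = [
    "SimConfig",
    "CONFIG_PROFILES",
    "simulate_lc",
    "config_profiles",
    "simulate_ranking",
    "run_ri_study",
]


@dataclass(frozen=True)
class SimConfig:
    """Generating model for multinomial latent class data.

    ``profiles`` is ``(K, J)`` of P(category 1) for binary items, or a list of
    ``(K, C_j)`` category-probability matrices for general items.
    """

    n_cases: int
    class_sizes: np.ndarray
    profiles: object
    seed: int | None = None
    n_replications: int = 100

    def __post_init__(self) -> None:
        sizes = np.asarray(self.class_sizes, dtype=float)
        if sizes.ndim != 1 or (sizes <= 0).any() or abs(sizes.sum() - 1) > 1e-8:
            raise ValueError("class_sizes must be positive and sum to 1")
        if isinstance(self.profiles, np.ndarray) and self.profiles.ndim == 2:
            prof = np.asarray(self.profiles, dtype=float)
            if prof.shape[0] != sizes.size:
                raise ValueError("profiles must have one row per class")
            if (prof < 0).any() or (prof > 1).any():
                raise ValueError("profiles must be probabilities in [0, 1]")
            object.__setattr__(self, "profiles", prof)
        else:
            prof = [np.asarray(p, dtype=float) for p in self.profiles]
            for j, p in enumerate(prof):
                if p.shape[0] != sizes.size or (p < 0).any():
                    raise ValueError(f"profiles[{j}] must be (K, C_j) probabilities")
                if np.abs(p.sum(axis=1) - 1).max() > 1e-8:
                    raise ValueError(f"profiles[{j}] rows must sum to 1")
            object.__setattr__(self, "profiles", tuple(prof))
        object.__setattr__(self, "class_sizes", sizes)
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")

    @property
    def n_classes(self) -> int:
        return self.class_sizes.size


# The simulation-study dimensions: 1,000 cases, 10 dichotomous items, equal
# class sizes. Category 1 is the "positive" response.
_BASE_N = 1000

CONFIG_PROFILES: dict[str, np.ndarray] = {
    # one distinct class; two similar mirror-image classes averaging 0.2 on
    # every item (+/-0.1), separable only at the second level of a tree
    "A": np.array([
        [0.8] * 10,
        [0.3] * 5 + [0.1] * 5,
        [0.1] * 5 + [0.3] * 5,
    ]),
    # three mutually distinct classes
    "B": np.array([
        [0.8] * 10,
        [0.2] * 10,
        [0.8] * 5 + [0.2] * 5,
    ]),
    # two macro-clusters with pair means 0.8 and 0.2; the pairs differ by
    # +/-0.16 on disjoint item subsets (1-5 for the high pair, 6-10 for the
    # low pair), enough for BIC to resolve each pair at n=1,000
    "C": np.array([
        [0.96] * 5 + [0.8] * 5,
        [0.64] * 5 + [0.8] * 5,
        [0.2] * 5 + [0.36] * 5,
        [0.2] * 5 + [0.04] * 5,
    ]),
}


def config_profiles(name: str) -> SimConfig:
    """Built-in study configuration A, B, or C (equal class sizes, n=1,000)."""
    key = name.upper()
    if key not in CONFIG_PROFILES:
        raise ValueError(f"unknown configuration {name!r}; choose from A, B, C")
    prof = CONFIG_PROFILES[key]
    k = prof.shape[0]
    return SimConfig(
        n_cases=_BASE_N,
        class_sizes=np.full(k, 1.0 / k),
        profiles=prof.copy(),
    )


def simulate_lc(config: SimConfig, seed: int | None = None) -> CategoricalDataset:
    """Draw one dataset: class labels from ``class_sizes``, then responses
    independently per item given class. Unit case weights; reproducible given
    the seed (``seed`` overrides ``config.seed``)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_cases
    labels = rng.choice(config.n_classes, size=n, p=config.class_sizes)
    if isinstance(config.profiles, np.ndarray):
        p1 = config.profiles[labels]                      # (n, J)
        resp = np.where(rng.random(p1.shape) < p1, 1, 2)
    else:
        cols = []
        for p in config.profiles:
            cum = np.cumsum(p[labels], axis=1)            # (n, C_j)
            u = rng.random((n, 1))
            cols.append(1 + (u > cum[:, :-1]).sum(axis=1))
        resp = np.column_stack(cols)
    ncat = (np.full(resp.shape[1], 2) if isinstance(config.profiles, np.ndarray)
            else np.array([p.shape[1] for p in config.profiles]))
    return CategoricalDataset.from_arrays(resp, n_categories=ncat)


def simulate_ranking(params: RankingParameters, n: int,
                     seed: int | None = None) -> RankingDataset:
    """Draw top-2 choice data: class from the proportions, then per item a
    first choice over all alternatives and a second over the remainder, with
    class-specific utilities shared between the two stages."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(params.n_classes, size=n, p=params.proportions)
    first = np.empty((n, len(params.logits)), dtype=np.int64)
    second = np.empty_like(first)
    for j, beta in enumerate(params.logits):
        tau = np.exp(beta - beta.max(axis=1, keepdims=True))
        p_first = tau / tau.sum(axis=1, keepdims=True)    # (K, A)
        pf = p_first[labels]                              # (n, A)
        u = rng.random((n, 1))
        a1 = (u > np.cumsum(pf, axis=1)[:, :-1]).sum(axis=1)
        ps = pf.copy()
        ps[np.arange(n), a1] = 0.0
        ps /= ps.sum(axis=1, keepdims=True)
        u = rng.random((n, 1))
        a2 = (u > np.cumsum(ps, axis=1)[:, :-1]).sum(axis=1)
        first[:, j] = a1 + 1
        second[:, j] = a2 + 1
    return RankingDataset.from_arrays(first, second)


def run_ri_study(
    config_name: str,
    n_replications: int = 20,
    Kmax: int = 4,
    seed: int | None = None,
    **fit_options,
) -> pd.DataFrame:
    """Replicate the root-size simulation study for one configuration.

    Per replication: simulate a dataset, fit 1..Kmax-class models, and record
    the relative log-likelihood improvements RI_{2,3} (and RI_{3,4} when
    Kmax >= 4). Returns one row per replication with the log-likelihoods, the
    RI values, and a convergence flag; summary statistics are left to the
    caller (``DataFrame.describe`` or the CLI).
    """
    if Kmax < 3:
        raise ValueError("Kmax must be >= 3 to compute RI_{2,3}")
    base = config_profiles(config_name)
    master = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(master.spawn(n_replications)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        data = simulate_lc(replace(base, seed=rep_seed))
        tab = fit_table(data, Kmax, seed=rep_seed, **fit_options)
        ri = relative_improvement(tab, "loglik")
        row = {"replication": rep, "seed": rep_seed}
        for k in range(1, Kmax + 1):
            row[f"loglik_{k}"] = tab.frame.loc[k, "loglik"]
        row["ri_2_3"] = ri.values[2]
        if Kmax >= 4:
            row["ri_3_4"] = ri.values[3]
        row["converged"] = bool(tab.frame["converged"].all())
        rows.append(row)
    return pd.DataFrame(rows)
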