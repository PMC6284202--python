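"""Containers for integer-coded categorical response data with case weights.

Responses are coded ``1..C_j`` per item (the social-science file convention);
all internal computation subtracts 1 to index probability tables. Case weights
are nonnegative reals; in a latent class tree they carry the posterior mass a
case contributes to a node, so a dataset is always the *full* sample and node
membership is expressed purely through the weight vector.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CategoricalDataset:
    """An ``N x J`` table of categorical responses plus per-case weights.

    Parameters
    ----------
    responses
        Integer array of shape ``(N, J)`` with codes in ``1..C_j`` for item j.
    weights
        Nonnegative reals of length N; at least one must be positive.
    item_labels
        J item names (defaults to ``item1..itemJ``).
    n_categories
        Number of categories ``C_j >= 2`` per item (defaults to the observed
        maximum code, but at least 2).
    """

    responses: np.ndarray
    weights: np.ndarray
    item_labels: tuple[str, ...]
    n_categories: np.ndarray

    def __post_init__(self) -> None:
        resp = np.asarray(self.responses)
        if resp.ndim != 2 or resp.shape[0] < 1 or resp.shape[1] < 1:
            raise ValueError("responses must be a 2-D array with N, J >= 1")
        if np.issubdtype(resp.dtype, np.floating):
            if np.isnan(resp).any():
                i, j = np.argwhere(np.isnan(resp))[0]
                raise ValueError(
                    f"missing response at row {i}, column {self.item_labels[j]!r}: "
                    "missing data are not supported; drop or impute first"
                )
            if not np.array_equal(resp, resp.astype(np.int64)):
                raise ValueError("responses must be integer category codes")
        resp = resp.astype(np.int64)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (resp.shape[0],):
            raise ValueError("weights must be a length-N vector")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if not (w > 0).any():
            raise ValueError("at least one weight must be positive")
        ncat = np.asarray(self.n_categories, dtype=np.int64)
        if ncat.shape != (resp.shape[1],) or (ncat < 2).any():
            raise ValueError("n_categories must be length J with C_j >= 2")
        if (resp < 1).any():
            i, j = np.argwhere(resp < 1)[0]
            raise ValueError(
                f"invalid response code at row {i}, column {self.item_labels[j]!r}: "
                "codes must be >= 1"
            )
        if (resp > ncat[None, :]).any():
            i, j = np.argwhere(resp > ncat[None, :])[0]
            raise ValueError(
                f"response code at row {i}, column {self.item_labels[j]!r} "
                f"exceeds declared category count {ncat[j]}"
            )
        if len(self.item_labels) != resp.shape[1]:
            raise ValueError("item_labels must have one entry per item")
        object.__setattr__(self, "responses", resp)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "n_categories", ncat)
        object.__setattr__(self, "item_labels", tuple(self.item_labels))

    @classmethod
    def from_arrays(
        cls,
        responses,
        weights=None,
        item_labels=None,
        n_categories=None,
    ) -> "CategoricalDataset":
        resp = np.asarray(responses)
        if resp.ndim != 2:
            raise ValueError("responses must be 2-D")
        n, j = resp.shape
        if weights is None:
            weights = np.ones(n)
        if item_labels is None:
            item_labels = tuple(f"item{q + 1}" for q in range(j))
        if n_categories is None:
            n_categories = np.maximum(resp.max(axis=0), 2)
        return cls(resp, np.asarray(weights, dtype=float), tuple(item_labels),
                   np.asarray(n_categories))

    @property
    def n_cases(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def with_weights(self, weights) -> "CategoricalDataset":
        """Return a copy carrying a different case-weight vector."""
        return dataclasses.replace(self, weights=np.asarray(weights, dtype=float))
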