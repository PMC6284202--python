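"""Reading and writing delimited data, fit tables, and trees.

Input files are delimited text with a header row; the separator is sniffed
from the extension (``.tsv`` means tab, anything else comma) and can be
overridden. Category and choice codes are 1-based in files, matching common
social-science coding.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CategoricalDataset
from .ranking import RankingDataset
from .selection import FitTable, fit_table_frame
from .tree import LatentClassTree

__all__ = [
    "read_categorical",
    "write_categorical",
    "read_ranking",
    "write_fit_table",
    "write_tree",
    "read_tree_json",
    "write_manifest",
]


def _sep_for(path, sep):
    if sep is not None:
        return sep
    return "\t" if str(path).endswith(".tsv") else ","


def _read_frame(path, sep):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if df.empty:
        raise ValueError(f"{path} contains no data rows")
    return df


def _check_missing(df: pd.DataFrame, cols) -> None:
    for col in cols:
        na = df[col].isna()
        if na.any():
            row = int(np.nonzero(na.to_numpy())[0][0])
            raise ValueError(
                f"missing value at row {row}, column {col!r}; "
                "missing data are not supported"
            )


def read_categorical(
    path,
    variables: list[str] | None = None,
    weight: str | None = None,
    sep: str | None = None,
    n_categories=None,
) -> CategoricalDataset:
    """Read a case-by-variable table of 1-based integer category codes.

    ``variables`` selects the item columns (default: all columns except the
    weight column); ``weight`` names an optional case-weight column. Missing
    cells are rejected with the offending row and column named.
    """
    df = _read_frame(path, sep)
    if variables is None:
        variables = [c for c in df.columns if c != weight]
    missing_cols = [c for c in variables if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path}: {missing_cols}")
    _check_missing(df, variables)
    weights = None
    if weight is not None:
        if weight not in df.columns:
            raise ValueError(f"weight column {weight!r} not found in {path}")
        _check_missing(df, [weight])
        weights = df[weight].to_numpy(dtype=float)
    resp = df[variables].to_numpy()
    return CategoricalDataset.from_arrays(
        resp, weights=weights, item_labels=tuple(variables),
        n_categories=n_categories,
    )


def write_categorical(data: CategoricalDataset, path, sep: str | None = None,
                      weight: str | None = None) -> None:
    """Write a dataset back to delimited text (inverse of read_categorical)."""
    df = pd.DataFrame(data.responses, columns=list(data.item_labels))
    if weight is not None:
        df[weight] = data.weights
    df.to_csv(path, sep=_sep_for(path, sep), index=False)


def read_ranking(
    path,
    items: list[tuple[str, str]],
    weight: str | None = None,
    sep: str | None = None,
    n_alternatives=None,
) -> RankingDataset:
    """Read top-2 choice data; ``items`` pairs (first, second) column names."""
    df = _read_frame(path, sep)
    cols = [c for pair in items for c in pair]
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"columns not found in {path}: {missing_cols}")
    _check_missing(df, cols)
    first = df[[a for a, _ in items]].to_numpy()
    second = df[[b for _, b in items]].to_numpy()
    weights = None
    if weight is not None:
        if weight not in df.columns:
            raise ValueError(f"weight column {weight!r} not found in {path}")
        _check_missing(df, [weight])
        weights = df[weight].to_numpy(dtype=float)
    labels = tuple(a for a, _ in items)
    return RankingDataset.from_arrays(first, second, weights=weights,
                                      item_labels=labels,
                                      n_alternatives=n_alternatives)


def write_fit_table(fit_tab: FitTable, path, *, rounded: bool = True) -> None:
    """Write the fit/RI table CSV: K, logL, P, BIC, AIC, RLL, RBIC, RAIC."""
    fit_table_frame(fit_tab, rounded=rounded).to_csv(path, index=False)


def write_tree(tree: LatentClassTree, path, format: str = "json") -> None:
    """Export a tree as JSON (full node fields) or Graphviz DOT."""
    path = Path(path)
    if format == "json":
        path.write_text(tree.to_json(indent=2) + "\n")
    elif format == "dot":
        path.write_text(tree.to_dot() + "\n")
    else:
        raise ValueError("format must be 'json' or 'dot'")


def read_tree_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_manifest(path, config: dict) -> None:
    """Record the run configuration, seeds, and library versions."""
    import click
    import scipy

    from . import __version__

    manifest = {
        "config": config,
        "versions": {
            "lctree": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "click": click.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
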