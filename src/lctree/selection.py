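"""Fit tables over a range of class counts and the relative-improvement rule.

To size the first (root) split of a latent class tree, standard LC models with
K = 1..Kmax classes are fitted to the full data and the *relative improvement*

    RI_{K,K+1} = (m_{K+1} - m_K) / (m_2 - m_1)

is computed, where m is the log-likelihood (or, with the sign flipped so that
improvement is positive, the decrease in BIC or AIC). The improvement from one
to two classes is the yardstick: a small RI means adding a (K+1)-th class buys
little relative to the dominant structure, so a K-class root suffices.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CategoricalDataset
from .lc import FitResult, IndicatorModel

__all__ = [
    "FitTable",
    "RITable",
    "fit_table",
    "relative_improvement",
    "ri_from_values",
    "select_root_size",
    "fit_table_frame",
]

MEASURES = ("loglik", "bic", "aic")


@dataclass
class FitTable:
    """Per-K fit statistics for K = 1..Kmax on one dataset."""

    frame: pd.DataFrame          # index K; columns loglik, n_params, bic, aic, converged
    n_total: int
    results: dict[int, FitResult] = field(default_factory=dict, repr=False)

    @property
    def kmax(self) -> int:
        return int(self.frame.index.max())


@dataclass
class RITable:
    """Relative improvements ``RI_{K,K+1}`` under one fit measure.

    ``values[K]`` is the improvement from K to K+1 classes relative to the
    improvement from 1 to 2; ``values[1]`` is 1 by construction.
    """

    measure: str
    values: dict[int, float]

    @property
    def kmax(self) -> int:
        return int(max(self.values)) + 1

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, name=f"RI({self.measure})")
        s.index.name = "K"
        return s.sort_index()


def fit_table(
    data: CategoricalDataset,
    Kmax: int,
    model=None,
    *,
    seed: int | None = None,
    **fit_options,
) -> FitTable:
    """Fit 1..Kmax-class models and tabulate logL, P, BIC, AIC.

    The per-K estimation seeds are derived deterministically from ``seed`` so
    the whole table is reproducible. A decrease in log-likelihood when adding
    a class (impossible at the global optimum) is flagged as a local-optimum
    warning.
    """
    if Kmax < 2:
        raise ValueError("Kmax must be at least 2 (the 1->2 baseline is needed)")
    if model is None:
        model = IndicatorModel()
    seeds = [int(s.generate_state(1)[0] % (2**31))
             for s in np.random.SeedSequence(seed).spawn(Kmax)]
    rows = []
    results: dict[int, FitResult] = {}
    for k in range(1, Kmax + 1):
        fit = model.fit(data, k, seed=seeds[k - 1], **fit_options)
        results[k] = fit
        rows.append({
            "loglik": fit.loglik, "n_params": fit.n_params,
            "bic": fit.bic, "aic": fit.aic, "converged": fit.converged,
        })
    frame = pd.DataFrame(rows, index=pd.RangeIndex(1, Kmax + 1, name="K"))
    ll = frame["loglik"].to_numpy()
    if (np.diff(ll) < -1e-6 * (np.abs(ll[:-1]) + 1)).any():
        warnings.warn(
            "log-likelihood decreased when adding a class; some fits are "
            "local optima — consider more starts", stacklevel=2,
        )
    return FitTable(frame=frame, n_total=data.n_cases, results=results)


def ri_from_values(values, measure: str = "loglik") -> RITable:
    """Relative improvements from a raw sequence of fit-measure values.

    ``values`` holds the measure for K = 1, 2, ... in order. For ``loglik``
    an improvement is an increase; for ``bic``/``aic`` it is a decrease. The
    denominator is the 1->2 improvement and must be strictly positive.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 2:
        raise ValueError("need fit values for at least K = 1 and 2")
    imp = np.diff(vals) if measure == "loglik" else -np.diff(vals)
    denom = imp[0]
    if denom <= 0:
        raise ValueError(
            f"improvement from 1 to 2 classes is not positive under {measure}; "
            "relative improvement is undefined"
        )
    ri = {k + 1: float(imp[k] / denom) for k in range(imp.size)}
    big = [k for k, v in ri.items() if k > 1 and v > 1 + 1e-12]
    if big:
        warnings.warn(
            f"RI exceeds 1 for K={big} under {measure}; reported as computed",
            stacklevel=2,
        )
    return RITable(measure=measure, values=ri)


def relative_improvement(fit_tab: FitTable, measure: str = "loglik") -> RITable:
    """Relative improvements computed from an estimated fit table."""
    return ri_from_values(fit_tab.frame[_column(measure)].to_numpy(), measure)


def _column(measure: str) -> str:
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    return measure


def select_root_size(ri_table: RITable, threshold: float = 0.10) -> int:
    """Smallest K >= 2 whose RI_{K,K+1} falls below ``threshold``.

    If no K qualifies, the largest K covered by the table is returned with a
    warning: the table simply was not extended far enough to see the
    improvement flatten out.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    ks = sorted(k for k in ri_table.values if k >= 2)
    if not ks:
        raise ValueError("RI table has no entries for K >= 2")
    for k in ks:
        if ri_table.values[k] < threshold:
            return k
    kmax = ks[-1] + 1
    warnings.warn(
        f"no K up to {kmax - 1} has RI below {threshold}; returning Kmax={kmax} "
        "— consider extending the fit table", stacklevel=2,
    )
    return kmax


def fit_table_frame(fit_tab: FitTable, *, rounded: bool = False) -> pd.DataFrame:
    """Fit table with RI columns in the conventional report layout.

    Columns are K, logL, P, BIC, AIC, RLL, RBIC, RAIC; the RI printed on row
    K is the improvement from K-1 to K classes (so row 2 reads 1.000). With
    ``rounded=True``, BIC/AIC are rounded to integers and RI to 3 decimals for
    display; RI values are always computed from the unrounded fits.
    """
    f = fit_tab.frame
    out = pd.DataFrame({
        "K": f.index, "logL": f["loglik"], "P": f["n_params"],
        "BIC": f["bic"], "AIC": f["aic"],
    }).set_index("K")
    for meas, col in (("loglik", "RLL"), ("bic", "RBIC"), ("aic", "RAIC")):
        out[col] = np.nan
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ri = relative_improvement(fit_tab, meas)
        except ValueError:
            continue
        for k, v in ri.values.items():
            out.loc[k + 1, col] = v
    if rounded:
        out["logL"] = out["logL"].round(0).astype(int)
        out["BIC"] = out["BIC"].round(0).astype(int)
        out["AIC"] = out["AIC"].round(0).astype(int)
        for col in ("RLL", "RBIC", "RAIC"):
            out[col] = out[col].round(3)
    return out.reset_index()
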