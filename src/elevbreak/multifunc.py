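"""Averaging ecosystem multifunctionality (EMF) and subset-robustness curves.

EMF collapses many ecosystem function measurements into one per-sample index:
each function column is Z-scored across samples and the per-sample mean of
Z-scores is the index.  Group EMFs average within functional groups, and the
subset curve probes how sensitive EMF is to the number of functions measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = ["zscore_table", "emf", "group_emf", "emf_subset_curve", "SubsetCurve"]


def zscore_table(function_table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise Z-scores ``(x - mean) / sd`` with the sample SD (n-1).

    Constant columns cannot be standardized and are rejected by name.
    """
    if len(function_table) < 2:
        raise ValueError("need at least 2 samples to Z-score")
    table = function_table.astype(float)
    sd = table.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant function column(s): {constant}")
    return (table - table.mean()) / sd


def emf(z: pd.DataFrame, function_subset=None, min_coverage: float = 0.5) -> pd.Series:
    """Per-sample EMF: row mean of Z-scores over the chosen functions.

    Missing entries are excluded pairwise; rows with less than
    ``min_coverage`` of the subset observed get a missing EMF.
    """
    cols = list(z.columns) if function_subset is None else list(function_subset)
    if not cols:
        raise ValueError("function subset must be non-empty")
    missing = [c for c in cols if c not in z.columns]
    if missing:
        raise KeyError(f"functions not in the Z table: {missing}")
    sub = z[cols]
    out = sub.mean(axis=1, skipna=True)
    coverage = sub.notna().mean(axis=1)
    out[coverage < min_coverage] = np.nan
    return out


def group_emf(z: pd.DataFrame, group_map: dict[str, str]) -> pd.DataFrame:
    """EMF per functional group; columns ordered by first appearance."""
    groups: dict[str, list[str]] = {}
    for fn, g in group_map.items():
        groups.setdefault(g, []).append(fn)
    return pd.DataFrame({g: emf(z, cols) for g, cols in groups.items()})


@dataclass
class SubsetCurve:
    """Distribution of subset-EMF and its agreement with the full index."""

    table: pd.DataFrame       # per (k, draw): mean/sd over samples + correlation
    k_values: np.ndarray
    correlation: pd.Series    # mean Pearson r with full EMF per k
    n_perm: int
    seed: int | None


def emf_subset_curve(z: pd.DataFrame, k_min: int = 10, k_max: int | None = None,
                     n_perm: int = 1000, seed: int | None = None) -> SubsetCurve:
    """EMF recomputed over random k-function subsets, k = k_min .. k_max.

    For each k, ``n_perm`` subsets are drawn uniformly without replacement
    within each subset (exhaustively when C(K, k) <= n_perm) and the Pearson
    correlation of each subset EMF with the full-set EMF is recorded.  At
    k = K the subset is the full set and the correlation is exactly 1.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    functions = list(z.columns)
    big_k = len(functions)
    k_max = big_k if k_max is None else k_max
    if k_max > big_k:
        raise ValueError("k_max exceeds the number of functions")
    full = emf(z)
    rng = np.random.default_rng(seed)

    rows = []
    corr_by_k = {}
    for k in range(k_min, k_max + 1):
        if comb(big_k, k) <= n_perm:
            subsets = [list(c) for c in combinations(functions, k)]
        else:
            subsets = [list(rng.choice(functions, size=k, replace=False))
                       for _ in range(n_perm)]
        correlations = []
        for i, subset in enumerate(subsets):
            e = emf(z, subset)
            if k == big_k:
                r = 1.0
            else:
                r = float(np.corrcoef(e, full)[0, 1]) if e.std() > 0 else np.nan
            correlations.append(r)
            rows.append({"k": k, "draw": i, "emf_mean": float(e.mean()),
                         "emf_sd": float(e.std(ddof=1)), "correlation": r})
        corr_by_k[k] = float(np.nanmean(correlations))

    return SubsetCurve(table=pd.DataFrame(rows),
                       k_values=np.arange(k_min, k_max + 1),
                       correlation=pd.Series(corr_by_k, name="correlation"),
                       n_perm=n_perm, seed=seed)
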