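"""Distances, ordinations and permutation tests on multivariate tables."""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = ["bray_curtis", "pca", "dca", "permanova",
           "OrdinationResult", "PermanovaResult"]

log = logging.getLogger(__name__)


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` between all sample pairs.

    Rows must be non-negative; zero-sum rows are rejected by name since their
    dissimilarity is undefined.
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    zero = matrix.index[x.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"zero-sum sample rows: {zero}")
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame            # samples x axes
    eigenvalues: np.ndarray
    percent_explained: np.ndarray
    method: str
    loadings: pd.DataFrame | None = None
    n_segments: int | None = None


def pca(table: pd.DataFrame, scale: bool = True) -> OrdinationResult:
    """Principal component analysis of a samples x variables table.

    Centered always; scaled to unit variance when ``scale`` (i.e. PCA of the
    correlation matrix — the default since geological variables carry mixed
    units).  Constant columns are dropped with a warning.  Axis sign follows
    the convention that the largest-magnitude loading is positive.
    """
    if len(table) < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = table.astype(float)
    sd = x.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        log.warning("pca: dropping constant column(s) %s", constant)
        x = x.drop(columns=constant)
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least 2 non-constant variables")
    xc = x - x.mean()
    if scale:
        xc = xc / x.std(ddof=1)
    u, s, vt = np.linalg.svd(xc.to_numpy(), full_matrices=False)
    eig = s ** 2 / (len(x) - 1)
    # sign convention: largest |loading| positive per axis
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    scores = u * s
    percent = 100.0 * eig / eig.sum()
    axes = [f"PC{k + 1}" for k in range(len(eig))]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=table.index, columns=axes),
        eigenvalues=eig,
        percent_explained=percent,
        method="PCA",
        loadings=pd.DataFrame(vt.T, index=x.columns, columns=axes),
    )


def _correspondence_analysis(x: np.ndarray):
    """CA of a non-negative matrix: row scores (principal coords) and eigenvalues."""
    total = x.sum()
    p = x / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sv, vt = np.linalg.svd(s, full_matrices=False)
    # drop the trivial near-zero tail
    eig = sv ** 2
    row_scores = (u / np.sqrt(r[:, None])) * sv[None, :]
    return row_scores, eig


def dca(matrix: pd.DataFrame, n_segments: int = 26) -> OrdinationResult:
    """Detrended correspondence analysis by segment-wise centering.

    Correspondence analysis (reciprocal averaging) gives the axes; axis 2 is
    then detrended against axis 1 by splitting the axis-1 range into
    ``n_segments`` equal segments and centering axis-2 scores within each
    segment.  Axis 1 itself is unchanged.  Hill's nonlinear rescaling is not
    applied, so scores are in raw CA units rather than SD units.
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("DCA requires a non-negative matrix")
    row_ok = x.sum(axis=1) > 0
    col_ok = x.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        log.warning("dca: dropping %d zero-sum rows and %d zero-sum columns",
                    (~row_ok).sum(), (~col_ok).sum())
    x = x[np.ix_(row_ok, col_ok)]
    if x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("too few non-empty rows/columns for DCA")

    row_scores, eig = _correspondence_analysis(x)
    ax1 = row_scores[:, 0]
    ax2 = row_scores[:, 1].copy()

    lo, hi = ax1.min(), ax1.max()
    if hi > lo:
        edges = np.linspace(lo, hi, n_segments + 1)
        seg = np.clip(np.searchsorted(edges, ax1, side="right") - 1, 0, n_segments - 1)
        for g in np.unique(seg):
            mask = seg == g
            ax2[mask] -= ax2[mask].mean()

    scores = pd.DataFrame(
        {"DCA1": ax1, "DCA2": ax2}, index=matrix.index[row_ok])
    return OrdinationResult(
        scores=scores,
        eigenvalues=eig[:2],
        percent_explained=100.0 * eig[:2] / eig.sum(),
        method="DCA",
        n_segments=n_segments,
    )


@dataclass
class PermanovaResult:
    pseudo_f: float
    ss_total: float
    ss_within: float
    ss_between: float
    df_between: int
    df_within: int
    n_permutations: int
    p_value: float
    seed: int | None = None
    exhaustive: bool = False


def _permanova_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple:
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        m = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(m, 1)].sum() / m
    ss_between = ss_total - ss_within
    g = len(groups)
    f = (ss_between / (g - 1)) / (ss_within / (n - g))
    return f, ss_total, ss_within, ss_between


def permanova(dist: pd.DataFrame, groups, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA pseudo-F with a permutation p-value.

    ``pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g))`` on squared
    distances, with ``SS_total = (1/n) sum_{i<j} d_ij^2`` and within-group
    sums over within-group pairs.  When the number of distinct label
    assignments is at most ``n_perm`` the null distribution is enumerated
    exhaustively (p = proportion of assignments with F >= F_obs, ties counted
    conservatively); otherwise random label permutations are drawn and the
    add-one rule ``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` applies.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = np.asarray(pd.Series(groups).reindex(dist.index)
                        if isinstance(groups, (pd.Series, dict)) else groups)
    if len(labels) != len(dist):
        raise ValueError("groups length must match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"group(s) of size 1 not allowed: {small}")

    d2 = dist.to_numpy(dtype=float) ** 2
    f_obs, ss_total, ss_within, ss_between = _permanova_f(d2, labels, uniq)

    n = len(labels)
    n_assign = math.factorial(n)
    for c in counts:
        n_assign //= math.factorial(int(c))
    if n_assign <= n_perm:
        # enumerate distinct assignments of labels to positions
        count = 0
        for perm in _distinct_assignments(labels):
            f_p, *_ = _permanova_f(d2, perm, uniq)
            if f_p >= f_obs - 1e-12:
                count += 1
        p = count / n_assign
        return PermanovaResult(f_obs, ss_total, ss_within, ss_between,
                               len(uniq) - 1, n - len(uniq), n_assign, p,
                               seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        f_p, *_ = _permanova_f(d2, rng.permutation(labels), uniq)
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(f_obs, ss_total, ss_within, ss_between,
                           len(uniq) - 1, n - len(uniq), n_perm, p, seed)


def _distinct_assignments(labels: np.ndarray):
    """Yield every distinct arrangement of the multiset of labels."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    slots = list(range(n))

    def rec(remaining_slots, k):
        if k == len(uniq):
            yield {}
            return
        for combo in itertools.combinations(remaining_slots, counts[k]):
            rest = [s for s in remaining_slots if s not in combo]
            for tail in rec(rest, k + 1):
                tail = dict(tail)
                for s in combo:
                    tail[s] = uniq[k]
                yield tail

    for assignment in rec(slots, 0):
        out = np.empty(n, dtype=labels.dtype)
        for s, lab in assignment.items():
            out[s] = lab
        yield out
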