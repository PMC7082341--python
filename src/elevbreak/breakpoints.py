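"""Elevational breakpoint detection and localization.

Four complementary lines of evidence, mirroring how abrupt ecological change
is located along a gradient in practice:

* :func:`piecewise_fit` — continuous two-segment ("broken-stick") regression
  of a single response on elevation, with the breakpoint found by grid search
  and a bootstrap confidence interval;
* :func:`adjacent_turnover` — Bray-Curtis dissimilarity and PERMANOVA between
  each pair of adjacent sites, selecting the pair with the strongest
  compositional turnover inside the candidate band;
* :func:`split_density` — a gradient-forest-style profile aggregating
  regression-tree split locations (one variance-reduction tree per taxon) into
  an importance-weighted density, standardized by the sampling density of
  elevations;
* :func:`cross_mountain` — matched-elevation community similarity between two
  transects, locating the similarity minimum and testing similarity-elevation
  slopes by permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .composition import bray_curtis, permanova, PermanovaResult
from .simulate import match_elevations

__all__ = [
    "BreakpointFit", "TurnoverProfile", "SplitDensity", "CrossMountainResult",
    "piecewise_fit", "breakpoint_bootstrap", "adjacent_turnover",
    "split_density", "cross_mountain", "consensus_breakpoints",
]

log = logging.getLogger(__name__)


@dataclass
class BreakpointFit:
    """Continuous two-segment fit y = b0 + b1*x + b2*(x - psi)_+ ."""

    psi: float
    beta0: float
    beta1: float
    beta2: float
    sse: float
    r2: float
    p_improvement: float
    band: tuple[float, float]
    n: int
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None
    edge_limited: bool = False


def _candidate_grid(x: np.ndarray, band: tuple[float, float], step: float) -> np.ndarray:
    lo, hi = float(band[0]), float(band[1])
    if hi < x.min() or lo > x.max():
        raise ValueError("breakpoint search band lies outside the data range")
    cand = np.arange(lo, hi + 0.5 * step, step)
    ux = np.sort(np.unique(x))
    n_below = np.searchsorted(ux, cand, side="left")
    n_above = len(ux) - np.searchsorted(ux, cand, side="right")
    cand = cand[(n_below >= 2) & (n_above >= 2)]
    if cand.size == 0:
        raise ValueError("no admissible breakpoint candidates in the band")
    return cand


def _grid_search(x: np.ndarray, y: np.ndarray, band: tuple[float, float],
                 step: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized SSE grid search; ``y`` may be (n,) or (n, R).

    Returns (psi_hat per response, sse at psi_hat per response).  All candidate
    models are solved at once through 3x3 normal equations on centred data;
    the winner is refit by least squares afterwards for reporting.
    """
    y2d = y[:, None] if y.ndim == 1 else y
    n, r = y2d.shape
    cand = _candidate_grid(x, band, step)
    xc = x - x.mean()
    yc = y2d - y2d.mean(axis=0)
    u = np.clip(x[None, :] - cand[:, None], 0.0, None)      # C x n
    c = len(cand)
    g = np.empty((c, 3, 3))
    g[:, 0, 0] = n
    g[:, 0, 1] = g[:, 1, 0] = 0.0
    g[:, 1, 1] = xc @ xc
    g[:, 0, 2] = g[:, 2, 0] = u.sum(axis=1)
    g[:, 1, 2] = g[:, 2, 1] = u @ xc
    g[:, 2, 2] = (u * u).sum(axis=1)
    b = np.empty((c, 3, r))
    b[:, 0, :] = 0.0
    b[:, 1, :] = xc @ yc
    b[:, 2, :] = u @ yc
    beta = np.linalg.solve(g, b)
    syy = (yc * yc).sum(axis=0)
    sse = syy[None, :] - np.einsum("ckr,ckr->cr", beta, b)
    best = np.argmin(sse, axis=0)
    return cand[best], sse[best, np.arange(r)]


def _refit(x: np.ndarray, y: np.ndarray, psi: float) -> tuple[np.ndarray, float]:
    design = np.column_stack([np.ones_like(x), x, np.clip(x - psi, 0.0, None)])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid)


def piecewise_fit(x, y, band: tuple[float, float] = (1800.0, 3000.0),
                  step: float = 1.0, n_boot: int = 0,
                  seed: int | None = None) -> BreakpointFit:
    """Fit a continuous two-segment regression with a grid-searched breakpoint.

    The breakpoint ``psi`` minimizes SSE over a grid (default 1 m step) inside
    ``band``; segments are forced continuous at ``psi``.  ``p_improvement``
    compares the piecewise model against a single line with an F-test charging
    the two extra parameters (slope change and breakpoint); because the
    breakpoint is searched, the test is approximate and its null calibration
    is checked by simulation rather than assumed.

    With ``n_boot > 0`` a case-resampling bootstrap percentile CI for ``psi``
    is attached (see :func:`breakpoint_bootstrap`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 6:
        raise ValueError("need at least 6 points for a piecewise fit")
    psi, _ = _grid_search(x, y, band, step)
    psi = float(psi[0]) if np.ndim(psi) else float(psi)
    beta, sse = _refit(x, y, psi)

    lin = np.column_stack([np.ones_like(x), x])
    bl, *_ = np.linalg.lstsq(lin, y, rcond=None)
    resid0 = y - lin @ bl
    sse0 = float(resid0 @ resid0)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    n = len(x)
    if sse <= 0:
        p_improve = 0.0
    else:
        f = ((sse0 - sse) / 2.0) / (sse / (n - 4))
        p_improve = float(stats.f.sf(max(f, 0.0), 2, n - 4))

    fit = BreakpointFit(psi=psi, beta0=float(beta[0]), beta1=float(beta[1]),
                        beta2=float(beta[2]), sse=sse, r2=r2,
                        p_improvement=p_improve, band=(float(band[0]), float(band[1])),
                        n=n, seed=seed)
    if n_boot > 0:
        lo, hi, edge = breakpoint_bootstrap(x, y, band, n_boot=n_boot,
                                            seed=seed, step=step)
        fit.ci_low, fit.ci_high, fit.edge_limited, fit.n_boot = lo, hi, edge, n_boot
    return fit


def breakpoint_bootstrap(x, y, band: tuple[float, float] = (1800.0, 3000.0),
                         n_boot: int = 999, seed: int | None = None,
                         step: float = 1.0) -> tuple[float, float, bool]:
    """Case-resampling bootstrap percentile 95% CI for the breakpoint.

    Returns ``(ci_low, ci_high, edge_limited)``; the flag is set when more
    than 20% of bootstrap estimates land within one grid step of a band edge,
    indicating the interval is constrained by the search band rather than the
    data.  Replicates whose resample leaves no admissible candidate are
    skipped with a log message.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(x)
    psis = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            psi, _ = _grid_search(x[idx], y[idx], band, step)
        except ValueError:
            skipped += 1
            continue
        psis.append(float(psi[0]) if np.ndim(psi) else float(psi))
    if skipped:
        log.warning("breakpoint_bootstrap: %d replicate(s) had no admissible candidates",
                    skipped)
    psis = np.asarray(psis)
    lo, hi = np.percentile(psis, [2.5, 97.5])
    at_edge = (psis <= band[0] + step) | (psis >= band[1] - step)
    edge_limited = bool(at_edge.mean() > 0.2)
    if edge_limited:
        log.warning("breakpoint_bootstrap: CI edge-limited (%.0f%% of fits at band edge)",
                    100 * at_edge.mean())
    return float(lo), float(hi), edge_limited


@dataclass
class TurnoverProfile:
    """Adjacent-site turnover statistics and the selected breakpoint pair."""

    table: pd.DataFrame          # one row per adjacent site pair
    selected: dict               # the chosen pair's row as a dict
    band: tuple[float, float]

    @property
    def breakpoint_elev(self) -> float:
        """Midpoint elevation between the selected pair of sites."""
        return float(self.selected["boundary_elev"])


def adjacent_turnover(matrix: pd.DataFrame, site_of_sample: pd.Series,
                      site_elevations: dict | pd.Series,
                      band: tuple[float, float] = (1800.0, 3000.0),
                      n_perm: int = 999, seed: int | None = None) -> TurnoverProfile:
    """Compositional turnover between every pair of adjacent sites.

    For each adjacent pair (sites ordered by elevation): the mean between-site
    Bray-Curtis dissimilarity and a two-group PERMANOVA.  The breakpoint pair
    is the one inside the band maximizing the sum of within-band ranks of
    pseudo-F and dissimilarity (higher pseudo-F wins ties) — the "highest
    pseudo-F and dissimilarity" turnover rule.
    """
    site_of_sample = pd.Series(site_of_sample, index=matrix.index)
    elev = pd.Series(site_elevations).astype(float)
    sites = elev.sort_values().index.tolist()
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")

    dist = bray_curtis(matrix)
    seeds = np.random.SeedSequence(seed).spawn(len(sites) - 1)
    rows = []
    for k in range(len(sites) - 1):
        a, b = sites[k], sites[k + 1]
        ia = matrix.index[site_of_sample == a]
        ib = matrix.index[site_of_sample == b]
        if len(ia) < 2 or len(ib) < 2:
            raise ValueError(f"sites {a!r}/{b!r} need >= 2 samples each")
        between = dist.loc[ia, ib].to_numpy().mean()
        sub = dist.loc[ia.append(ib), ia.append(ib)]
        labels = np.array([0] * len(ia) + [1] * len(ib))
        pr: PermanovaResult = permanova(sub, labels, n_perm=n_perm,
                                        seed=int(seeds[k].generate_state(1)[0] % 2**31))
        rows.append({
            "site_low": a, "site_high": b,
            "elev_low": elev[a], "elev_high": elev[b],
            "boundary_elev": 0.5 * (elev[a] + elev[b]),
            "dissimilarity": between,
            "pseudo_f": pr.pseudo_f, "p_value": pr.p_value,
        })
    table = pd.DataFrame(rows)

    in_band = table[(table["boundary_elev"] >= band[0])
                    & (table["boundary_elev"] <= band[1])]
    if in_band.empty:
        raise ValueError("no adjacent pair falls inside the breakpoint band")
    score = (in_band["pseudo_f"].rank() + in_band["dissimilarity"].rank())
    best = in_band.loc[score == score.max()]
    if len(best) > 1:
        best = best.sort_values("pseudo_f", ascending=False)
    selected = best.iloc[0].to_dict()
    return TurnoverProfile(table=table, selected=selected,
                           band=(float(band[0]), float(band[1])))


@dataclass
class SplitDensity:
    """Importance-weighted regression-tree split density along elevation."""

    grid: np.ndarray
    raw_density: np.ndarray
    data_density: np.ndarray
    standardized: np.ndarray
    peak_elev: float | None
    splits: pd.DataFrame         # taxon, threshold, weight


def _silverman(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    if weights is None:
        weights = np.ones_like(values)
    w = weights / weights.sum()
    mean = w @ values
    sd = np.sqrt(w @ (values - mean) ** 2)
    n_eff = 1.0 / np.sum(w ** 2)
    q75, q25 = np.percentile(values, [75, 25])
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread <= 0:
        return 50.0  # degenerate split set: a narrow fixed kernel (m)
    return 0.9 * spread * n_eff ** (-0.2)


def _weighted_kde(grid: np.ndarray, values: np.ndarray,
                  weights: np.ndarray, bandwidth: float) -> np.ndarray:
    z = (grid[:, None] - values[None, :]) / bandwidth
    k = np.exp(-0.5 * z * z) / (bandwidth * np.sqrt(2 * np.pi))
    w = weights / weights.sum()
    return k @ w


def split_density(matrix: pd.DataFrame, elevation, max_depth: int = 3,
                  min_leaf: int = 5, bandwidth: float | None = None,
                  grid_size: int = 512) -> SplitDensity:
    """Where do regression trees split elevation, across many taxa?

    One binary variance-reduction tree per taxon is fit on elevation alone;
    each split contributes its threshold weighted by the impurity decrease it
    achieves, weights normalized per taxon so abundant and rare taxa count
    equally.  Thresholds are pooled into a Gaussian kernel density (Silverman
    bandwidth by default) and standardized by the kernel density of the
    observed elevations, so peaks mark genuine change zones rather than
    sampling density.  Constant taxa contribute no splits.
    """
    elev = np.asarray(elevation, dtype=float)
    if len(elev) != len(matrix):
        raise ValueError("elevation length must match the matrix rows")
    if len(elev) < 2 * min_leaf:
        raise ValueError("too few samples for the requested min_leaf")

    records = []
    xcol = elev.reshape(-1, 1)
    for taxon in matrix.columns:
        y = matrix[taxon].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            continue
        tree = DecisionTreeRegressor(max_depth=max_depth,
                                     min_samples_leaf=min_leaf).fit(xcol, y)
        t = tree.tree_
        internal = np.flatnonzero(t.children_left != -1)
        if internal.size == 0:
            continue
        gains = []
        for node in internal:
            left, right = t.children_left[node], t.children_right[node]
            gain = (t.weighted_n_node_samples[node] * t.impurity[node]
                    - t.weighted_n_node_samples[left] * t.impurity[left]
                    - t.weighted_n_node_samples[right] * t.impurity[right])
            gains.append(max(gain, 0.0))
        gains = np.asarray(gains)
        if gains.sum() <= 0:
            continue
        for node, gain in zip(internal, gains / gains.sum()):
            records.append({"taxon": taxon, "threshold": float(t.threshold[node]),
                            "weight": float(gain)})

    splits = pd.DataFrame(records, columns=["taxon", "threshold", "weight"])
    grid = np.linspace(elev.min(), elev.max(), grid_size)
    h_data = bandwidth or _silverman(elev)
    data_density = _weighted_kde(grid, elev, np.ones_like(elev), h_data)

    if splits.empty:
        zero = np.zeros_like(grid)
        return SplitDensity(grid=grid, raw_density=zero, data_density=data_density,
                            standardized=zero, peak_elev=None, splits=splits)

    values = splits["threshold"].to_numpy()
    weights = splits["weight"].to_numpy()
    h = bandwidth or _silverman(values, weights)
    raw = _weighted_kde(grid, values, weights, h)
    standardized = raw / np.clip(data_density, 1e-300, None)
    peak = float(grid[np.argmax(standardized)])
    return SplitDensity(grid=grid, raw_density=raw, data_density=data_density,
                        standardized=standardized, peak_elev=peak, splits=splits)


@dataclass
class CrossMountainResult:
    """Matched-elevation similarity between two transects."""

    matched: pd.DataFrame        # elev_a, elev_b, similarity
    min_similarity_elev: float | None
    flat: bool
    slopes: pd.DataFrame         # per focal site of mountain B, per side


def cross_mountain(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                   elev_a, elev_b, pairing_tol: float = 100.0,
                   breakpoint: float | None = None, n_perm: int = 999,
                   seed: int | None = None) -> CrossMountainResult:
    """Compare two mountains' site-level communities at matched elevations.

    Taxon vocabularies are outer-joined with zero fill.  (i) Sites are paired
    by nearest elevation within ``pairing_tol``; the similarity
    (1 - Bray-Curtis) profile and its minimum are reported (a flat profile is
    flagged, leaving the minimum undefined).  (ii) When a ``breakpoint`` is
    given, each mountain-B site's similarities to all mountain-A sites below
    (and, separately, above) the breakpoint are regressed on mountain-A
    elevation, with permutation p-values on the slope.
    """
    from .drivers import permutation_lm

    elev_a = np.asarray(elev_a, dtype=float)
    elev_b = np.asarray(elev_b, dtype=float)
    cols = matrix_a.columns.union(matrix_b.columns)
    a = matrix_a.reindex(columns=cols, fill_value=0.0)
    b = matrix_b.reindex(columns=cols, fill_value=0.0)

    pairs = match_elevations(elev_a, elev_b, pairing_tol)
    if len(pairs) < 3:
        raise ValueError("fewer than 3 matched site pairs within tolerance")

    def bc(u: np.ndarray, v: np.ndarray) -> float:
        return float(np.abs(u - v).sum() / (u + v).sum())

    rows = []
    for p in pairs:
        sim = 1.0 - bc(a.iloc[p["site_a"]].to_numpy(), b.iloc[p["site_b"]].to_numpy())
        rows.append({"elev_a": p["elev_a"], "elev_b": p["elev_b"],
                     "elev": 0.5 * (p["elev_a"] + p["elev_b"]), "similarity": sim})
    matched = pd.DataFrame(rows)
    flat = bool(np.ptp(matched["similarity"].to_numpy()) < 1e-12)
    min_elev = None if flat else float(matched.loc[matched["similarity"].idxmin(), "elev"])

    slope_rows = []
    if breakpoint is not None:
        seeds = np.random.SeedSequence(seed).spawn(2 * len(elev_b))
        k = 0
        for j in range(len(elev_b)):
            for side, mask in (("below", elev_a < breakpoint),
                               ("above", elev_a >= breakpoint)):
                s = int(seeds[k].generate_state(1)[0] % 2**31)
                k += 1
                if mask.sum() < 3:
                    continue
                sims = np.array([1.0 - bc(a.iloc[i].to_numpy(), b.iloc[j].to_numpy())
                                 for i in np.flatnonzero(mask)])
                slope, pval = permutation_lm(elev_a[mask], sims, n_perm=n_perm, seed=s)
                slope_rows.append({"site_b": j, "elev_b": float(elev_b[j]),
                                   "side": side, "slope": slope, "p_value": pval,
                                   "n_sites_a": int(mask.sum())})
    slopes = pd.DataFrame(slope_rows,
                          columns=["site_b", "elev_b", "side", "slope", "p_value",
                                   "n_sites_a"])
    return CrossMountainResult(matched=matched, min_similarity_elev=min_elev,
                               flat=flat, slopes=slopes)


def consensus_breakpoints(fits: dict[str, list[BreakpointFit]],
                          alpha: float = 0.05) -> pd.DataFrame:
    """Summarize breakpoint estimates per facet (boxplot-style statistics)."""
    rows = []
    for facet, facet_fits in fits.items():
        if not facet_fits:
            raise ValueError(f"facet {facet!r} has no fits")
        psis = np.array([f.psi for f in facet_fits])
        rows.append({
            "facet": facet,
            "n": len(psis),
            "mean": float(psis.mean()),
            "median": float(np.median(psis)),
            "q1": float(np.percentile(psis, 25)),
            "q3": float(np.percentile(psis, 75)),
            "n_significant": int(sum(f.p_improvement < alpha for f in facet_fits)),
        })
    return pd.DataFrame(rows).set_index("facet")
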