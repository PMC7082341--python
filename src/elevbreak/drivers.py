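"""Attribution of variance to contemporary vs. geological predictor blocks.

Tools for the "what drives the pattern" half of the analysis: geochemical
weathering indices, predictor dereplication, AICc all-subsets model averaging
with Akaike weights, stepwise regressions quantifying the explained-variance
increment from geological predictors, variation partitioning over two
predictor blocks, composite variables, and recursive least-squares path
analysis with direct/indirect effect decomposition and SRMR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "geochem_indices", "dereplicate_predictors", "all_subsets_average",
    "geo_increment", "variation_partition", "composite_score", "path_fit",
    "permutation_lm", "ModelAverageResult", "IncrementResult",
    "VariancePartition", "PathModel",
]

log = logging.getLogger(__name__)


def geochem_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Weathering indices per sample.

    CIA (chemical index of alteration) = 100 * Al2O3 / (Al2O3 + CaO* + Na2O
    + K2O) on molar oxide proportions, with CaO* the silicate-fraction CaO
    (correction applied upstream); plus the elemental Ti/Fe, Ti/Al, Mg/Al and
    Ca/Al ratios.  Zero denominators yield missing values with a warning.
    """
    out = pd.DataFrame(index=table.index)
    denom = table[["al2o3", "cao_star", "na2o", "k2o"]].sum(axis=1)
    bad = denom <= 0
    if bad.any():
        log.warning("geochem_indices: %d sample(s) with non-positive CIA denominator",
                    int(bad.sum()))
    out["cia"] = np.where(bad, np.nan, 100.0 * table["al2o3"] / denom.replace(0, np.nan))
    for num, den, name in (("ti", "fe", "ti_fe"), ("ti", "al", "ti_al"),
                           ("mg", "al", "mg_al"), ("ca", "al", "ca_al")):
        d = table[den]
        zero = d == 0
        if zero.any():
            log.warning("geochem_indices: %d sample(s) with zero %s", int(zero.sum()), den)
        out[name] = table[num] / d.replace(0, np.nan)
    return out


def dereplicate_predictors(predictors: pd.DataFrame, response: pd.Series,
                           r_threshold: float = 0.7,
                           keep: str = "response") -> tuple[pd.DataFrame, list[str]]:
    """Drop one of every predictor pair correlated above the threshold.

    Pairs with Pearson ``|r|`` strictly above ``r_threshold`` conflict
    (``|r| == r_threshold`` keeps both); conflicts are resolved greedily from
    the strongest correlation down, keeping the member with the larger
    absolute correlation with the response (``keep='response'``, default) or
    simply the earlier column (``keep='first'``).  Returns the retained table
    and a human-readable decision log.
    """
    if predictors.shape[1] < 2:
        return predictors, []
    corr = predictors.corr().abs()
    resp_r = predictors.corrwith(response).abs()
    retained = list(predictors.columns)
    decisions: list[str] = []

    while True:
        # strictly above the threshold; the epsilon keeps |r| == threshold
        # (e.g. exactly 0.7) on the "keep both" side despite float round-off
        pairs = [(corr.loc[a, b], a, b)
                 for i, a in enumerate(retained) for b in retained[i + 1:]
                 if corr.loc[a, b] > r_threshold + 1e-10]
        if not pairs:
            break
        r, a, b = max(pairs)
        if keep == "first":
            drop, kept = b, a
        else:
            drop, kept = (b, a) if resp_r[a] >= resp_r[b] else (a, b)
        retained.remove(drop)
        decisions.append(
            f"dropped {drop} (|r|={r:.3f} with {kept}; "
            f"|r_response| {resp_r[drop]:.3f} vs {resp_r[kept]:.3f})")
    return predictors[retained], decisions


def _zscore(v: pd.Series | pd.DataFrame):
    return (v - v.mean()) / v.std(ddof=1)


def _ols(y: np.ndarray, x: np.ndarray) -> dict:
    """Least squares with intercept; returns coefs, SSE, R2, adjusted R2, AIC(c)."""
    n = len(y)
    design = np.column_stack([np.ones(n), x]) if x.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    p = design.shape[1] - 1          # predictors, excluding intercept
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
    k = p + 2                        # + intercept + error variance
    aic = n * math.log(max(sse, 1e-300) / n) + 2 * k
    aicc = aic + 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
    return {"beta": beta, "sse": sse, "r2": r2, "adj_r2": adj,
            "aic": aic, "aicc": aicc, "df_resid": n - p - 1}


@dataclass
class ModelAverageResult:
    models: pd.DataFrame          # subset, aicc, delta, weight
    beta: pd.Series               # conditional model-averaged standardized beta
    importance: pd.Series         # sum of weights over models containing each term
    dereplication_log: list[str] = field(default_factory=list)


def all_subsets_average(response: pd.Series, predictors: pd.DataFrame,
                        max_predictors: int = 15) -> ModelAverageResult:
    """AICc-weighted all-subsets regression with conditional averaging.

    Response and predictors are Z-scored, every predictor subset (including
    the null model) is fit by least squares, Akaike weights
    ``w_i = exp(-delta_i/2) / sum`` are formed from AICc, and each predictor's
    coefficient is averaged over only the models that contain it (conditional
    averaging).  Relative importance is the summed weight of those models.
    """
    names = list(predictors.columns)
    p = len(names)
    if p > max_predictors:
        raise ValueError(
            f"{p} predictors exceed max_predictors={max_predictors}; "
            "dereplicate or group predictors first")
    n = len(response)
    if n <= p + 2:
        raise ValueError("need n > #predictors + 2 observations")
    y = _zscore(response).to_numpy(dtype=float)
    xz = _zscore(predictors).to_numpy(dtype=float)

    rows = []
    betas: list[dict[str, float]] = []
    for k in range(p + 1):
        for subset in combinations(range(p), k):
            fit = _ols(y, xz[:, subset])
            rows.append({"subset": tuple(names[j] for j in subset), "aicc": fit["aicc"]})
            betas.append({names[j]: fit["beta"][i + 1] for i, j in enumerate(subset)})
    models = pd.DataFrame(rows)
    models["delta"] = models["aicc"] - models["aicc"].min()
    w = np.exp(-models["delta"] / 2.0)
    models["weight"] = w / w.sum()

    beta_avg, importance = {}, {}
    for name in names:
        contains = np.array([name in b for b in betas])
        w_in = models.loc[contains, "weight"].to_numpy()
        b_in = np.array([b[name] for b, c in zip(betas, contains) if c])
        importance[name] = float(w_in.sum())
        beta_avg[name] = float((w_in @ b_in) / w_in.sum())
    return ModelAverageResult(models=models,
                              beta=pd.Series(beta_avg, name="beta"),
                              importance=pd.Series(importance, name="importance"))


def _stepwise_aic(y: np.ndarray, x: pd.DataFrame, candidates: list[str],
                  locked: list[str] | None = None) -> list[str]:
    """Forward+backward selection by AIC from the null (or locked-in) model."""
    locked = list(locked or [])
    current: list[str] = []

    def aic_of(terms: list[str]) -> float:
        return _ols(y, x[locked + terms].to_numpy())["aic"] if (locked or terms) \
            else _ols(y, np.empty((len(y), 0)))["aic"]

    best_aic = aic_of(current)
    improved = True
    while improved:
        improved = False
        moves = [(aic_of(current + [c]), "add", c)
                 for c in candidates if c not in current]
        moves += [(aic_of([t for t in current if t != c]), "drop", c)
                  for c in current]
        if not moves:
            break
        aic_new, action, term = min(moves)
        if aic_new < best_aic - 1e-10:
            best_aic = aic_new
            if action == "add":
                current.append(term)
            else:
                current.remove(term)
            improved = True
    return current


def _nested_f(y: np.ndarray, x_small: np.ndarray, x_big: np.ndarray) -> tuple[float, float]:
    small = _ols(y, x_small)
    big = _ols(y, x_big)
    df1 = x_big.shape[1] - x_small.shape[1]
    df2 = big["df_resid"]
    if df1 <= 0 or df2 <= 0 or big["sse"] <= 0:
        return np.nan, np.nan
    f = ((small["sse"] - big["sse"]) / df1) / (big["sse"] / df2)
    return float(f), float(stats.f.sf(max(f, 0.0), df1, df2))


@dataclass
class IncrementResult:
    r2_contemporary: float
    r2_with_geology: float
    percent_increase: float | None
    absolute_increase: float
    f_statistic: float
    p_value: float
    selected_contemporary: list[str]
    selected_geological: list[str]
    significant_fraction: float | None = None


def geo_increment(response: pd.Series, contemporary: pd.DataFrame,
                  geological: pd.DataFrame, alpha: float = 0.05,
                  census: bool = True, max_census: int = 4096) -> IncrementResult:
    """How much explained variance do geological predictors add?

    A stepwise-AIC model is selected within the contemporary block; the
    geological block is then offered on top with the contemporary terms locked
    in.  The percent R-squared increase and a nested-model F-test quantify the
    geological contribution.  With ``census=True`` every contemporary-only
    subset is additionally augmented with the full geological block and the
    fraction of significant (alpha) improvements is reported.
    """
    overlap = set(contemporary.columns) & set(geological.columns)
    if overlap:
        raise ValueError(f"blocks must be disjoint; shared: {sorted(overlap)}")
    y = _zscore(response).to_numpy(dtype=float)
    x = pd.concat([_zscore(contemporary), _zscore(geological)], axis=1)

    sel_c = _stepwise_aic(y, x, list(contemporary.columns))
    sel_g = _stepwise_aic(y, x, list(geological.columns), locked=sel_c)
    fit_c = _ols(y, x[sel_c].to_numpy())
    fit_cg = _ols(y, x[sel_c + sel_g].to_numpy())
    r2_c, r2_cg = fit_c["r2"], fit_cg["r2"]
    # significance: ANOVA between the models excluding vs. including the full
    # geological block (fixed df, so the test stays calibrated — testing only
    # the stepwise-selected geological terms would inherit selection bias)
    f, p = _nested_f(y, x[sel_c].to_numpy(),
                     x[sel_c + list(geological.columns)].to_numpy())
    pct = 100.0 * (r2_cg - r2_c) / r2_c if r2_c > 0 else None
    if pct is None:
        log.warning("geo_increment: contemporary R2 is 0; percent increase undefined")

    frac = None
    if census:
        cnames = list(contemporary.columns)
        n_subsets = 2 ** len(cnames) - 1
        if n_subsets > max_census:
            raise ValueError("too many contemporary subsets for the census")
        geo = x[list(geological.columns)].to_numpy()
        sig = 0
        for k in range(1, len(cnames) + 1):
            for subset in combinations(cnames, k):
                base = x[list(subset)].to_numpy()
                _, p_sub = _nested_f(y, base, np.column_stack([base, geo]))
                sig += bool(p_sub < alpha)
        frac = sig / n_subsets
    return IncrementResult(r2_contemporary=r2_c, r2_with_geology=r2_cg,
                           percent_increase=pct,
                           absolute_increase=r2_cg - r2_c,
                           f_statistic=f, p_value=p,
                           selected_contemporary=sel_c,
                           selected_geological=sel_g,
                           significant_fraction=frac)


@dataclass
class VariancePartition:
    """Adjusted-R2 fractions: unique to A, unique to B, shared, residual."""

    a: float
    b: float
    c: float
    d: float
    adj_r2_a: float
    adj_r2_b: float
    adj_r2_ab: float


def variation_partition(response: pd.Series, block_a: pd.DataFrame,
                        block_b: pd.DataFrame) -> VariancePartition:
    """Variation partitioning of one response over two predictor blocks.

    Adjusted-R2 based: ``a = adjR2(AB) - adjR2(B)``, ``b = adjR2(AB) -
    adjR2(A)``, ``c = adjR2(A) + adjR2(B) - adjR2(AB)``, ``d = 1 -
    adjR2(AB)``.  The shared fraction c may legitimately be negative.
    """
    if block_a.shape[1] == 0 or block_b.shape[1] == 0:
        raise ValueError("both blocks must be non-empty")
    overlap = set(block_a.columns) & set(block_b.columns)
    if overlap:
        raise ValueError(f"blocks must be disjoint; shared: {sorted(overlap)}")
    y = response.to_numpy(dtype=float)
    ra = _ols(y, block_a.to_numpy(dtype=float))["adj_r2"]
    rb = _ols(y, block_b.to_numpy(dtype=float))["adj_r2"]
    rab = _ols(y, pd.concat([block_a, block_b], axis=1).to_numpy(dtype=float))["adj_r2"]
    if any(np.isnan(v) for v in (ra, rb, rab)):
        raise ValueError("singular or over-saturated fits in variation partitioning")
    return VariancePartition(a=rab - rb, b=rab - ra, c=ra + rb - rab, d=1.0 - rab,
                             adj_r2_a=ra, adj_r2_b=rb, adj_r2_ab=rab)


def composite_score(indicators: pd.DataFrame,
                    response: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Composite variable: regression-weighted sum of Z-scored indicators.

    Weights are the multiple-regression coefficients of the Z-scored response
    on the Z-scored indicators; the composite is re-standardized to unit SD.
    Collinear indicators should be dereplicated beforehand.
    """
    if indicators.shape[1] < 1:
        raise ValueError("need at least one indicator")
    xz = _zscore(indicators)
    if xz.isna().any().any():
        raise ValueError("constant indicator column(s)")
    y = _zscore(response).to_numpy(dtype=float)
    fit = _ols(y, xz.to_numpy(dtype=float))
    weights = pd.Series(fit["beta"][1:], index=indicators.columns, name="weight")
    raw = xz.to_numpy() @ weights.to_numpy()
    if np.std(raw, ddof=1) == 0:
        raise ValueError("composite has zero variance (degenerate weights)")
    composite = pd.Series(_zscore(pd.Series(raw, index=indicators.index)),
                          name="composite")
    return composite, weights


@dataclass
class PathModel:
    """Recursive least-squares path model over observed/composite variables."""

    nodes: list[str]
    edges: list[tuple[str, str]]
    coefficients: dict[tuple[str, str], float]
    r2: dict[str, float]
    direct: dict[str, float]
    indirect: dict[str, float]
    total: dict[str, float]
    srmr: float
    aic: float
    outcome: str


def _paths_to(edges_by_child: dict[str, list[str]], src: str, dst: str,
              coef: dict) -> list[float]:
    """Products of coefficients over every directed path src -> ... -> dst."""
    out: list[float] = []

    def walk(node: str, product: float) -> None:
        if node == src:
            out.append(product)
            return
        for parent in edges_by_child.get(node, []):
            walk(parent, product * coef[(parent, node)])

    walk(dst, 1.0)
    return out


def path_fit(data: pd.DataFrame, edges: list[tuple[str, str]],
             outcome: str) -> PathModel:
    """Fit a recursive (acyclic) path model by per-equation least squares.

    Every endogenous node is regressed on its parents after Z-scoring, giving
    standardized path coefficients.  Effects on the outcome decompose as
    direct (the edge coefficient into the outcome), indirect (the sum over
    all other directed paths of coefficient products), and total = direct +
    indirect.  Model fit is summarized by SRMR — the root-mean-square
    difference between observed and model-implied correlations — and by the
    summed per-equation AIC for comparing alternative path structures.
    """
    import networkx as nx

    g = nx.DiGraph(edges)
    if outcome not in g:
        raise ValueError(f"outcome {outcome!r} has no edges in the model")
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"path model contains a cycle: {cycle}")
    nodes = [n for n in data.columns if n in g.nodes]
    missing = [n for n in g.nodes if n not in data.columns]
    if missing:
        raise KeyError(f"model variables missing from the data: {missing}")

    z = _zscore(data[nodes])
    parents = {n: sorted(g.predecessors(n)) for n in nodes}
    coef: dict[tuple[str, str], float] = {}
    r2: dict[str, float] = {}
    resid_var: dict[str, float] = {}
    aic = 0.0
    n = len(z)
    for node in nodes:
        if not parents[node]:
            continue
        fit = _ols(z[node].to_numpy(), z[parents[node]].to_numpy())
        for parent, b in zip(parents[node], fit["beta"][1:]):
            coef[(parent, node)] = float(b)
        r2[node] = fit["r2"]
        resid_var[node] = fit["sse"] / (n - 1)
        aic += fit["aic"]

    # implied covariance of the recursive system y = B y + e, with the
    # exogenous block keeping its observed covariance
    idx = {v: i for i, v in enumerate(nodes)}
    p = len(nodes)
    bmat = np.zeros((p, p))
    for (a, bnode), v in coef.items():
        bmat[idx[bnode], idx[a]] = v
    psi = np.zeros((p, p))
    exo = [v for v in nodes if not parents[v]]
    obs_cov = z.cov().to_numpy()
    for u in exo:
        for v in exo:
            psi[idx[u], idx[v]] = obs_cov[idx[u], idx[v]]
    for v in nodes:
        if parents[v]:
            psi[idx[v], idx[v]] = resid_var[v]
    inv = np.linalg.inv(np.eye(p) - bmat)
    implied = inv @ psi @ inv.T
    dsqrt = np.sqrt(np.diag(implied))
    implied_corr = implied / np.outer(dsqrt, dsqrt)
    obs_corr = z.corr().to_numpy()
    iu = np.triu_indices(p, 1)
    srmr = float(np.sqrt(np.mean((obs_corr[iu] - implied_corr[iu]) ** 2)))

    edges_by_child = {c: ps for c, ps in parents.items() if ps}
    direct, indirect, total = {}, {}, {}
    for v in nodes:
        if v == outcome:
            continue
        d = coef.get((v, outcome), 0.0)
        products = _paths_to(edges_by_child, v, outcome, coef)
        ind = sum(products) - d  # all paths minus the direct edge
        direct[v], indirect[v], total[v] = d, ind, d + ind
    return PathModel(nodes=nodes, edges=list(g.edges), coefficients=coef, r2=r2,
                     direct=direct, indirect=indirect, total=total,
                     srmr=srmr, aic=aic, outcome=outcome)


def permutation_lm(x, y, n_perm: int = 4999,
                   seed: int | None = None) -> tuple[float, float]:
    """OLS slope of y on x with a permutation p-value on the slope.

    The response is permuted; p uses the add-one rule
    ``(1 + #{|slope_perm| >= |slope_obs|}) / (1 + n_perm)``, or exhaustive
    enumeration of all n! response orders when that is cheaper (p is then the
    exact proportion, the identity order included).  A constant response has
    slope 0 and p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("constant x: slope undefined")
    xc = x - x.mean()

    def slope_of(v: np.ndarray) -> float:
        return float(xc @ (v - v.mean()) / sxx)

    obs = slope_of(y)
    if np.ptp(y) == 0:
        return 0.0, 1.0
    n = len(y)
    tol = 1e-12 * max(abs(obs), 1.0)
    if math.factorial(n) <= n_perm:
        count = sum(abs(slope_of(np.asarray(p))) >= abs(obs) - tol
                    for p in permutations(y))
        return obs, count / math.factorial(n)
    rng = np.random.default_rng(seed)
    count = sum(abs(slope_of(rng.permutation(y))) >= abs(obs) - tol
                for _ in range(n_perm))
    return obs, (1 + count) / (1 + n_perm)
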