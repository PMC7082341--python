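"""Per-sample diversity and plant-survey quantities.

Community matrices are pandas DataFrames with samples as rows and taxa as
columns (non-negative counts or relative abundances).  Taxonomy maps are
DataFrames with ``taxon_id``, ``phylum`` and (for Proteobacteria) ``class``
columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "rarefy",
    "richness",
    "chao1",
    "aggregate_taxa",
    "prevalence_filter",
    "multidiversity",
    "importance_value",
    "plant_biomass",
    "MultidiversityResult",
]

log = logging.getLogger(__name__)


def rarefy(matrix: pd.DataFrame, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample every count row to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (with a logged
    warning) rather than scaled.  Subsampling is multivariate hypergeometric,
    i.e. classical rarefaction.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    counts = matrix.to_numpy()
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=1)
    keep = totals >= depth
    if not keep.all():
        dropped = list(matrix.index[~keep])
        log.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                    len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    rows = [row if row.sum() == depth else rng.multivariate_hypergeometric(row, depth)
            for row in counts[keep].astype(np.int64)]
    return pd.DataFrame(np.asarray(rows), index=matrix.index[keep], columns=matrix.columns)


def richness(row: np.ndarray | pd.Series) -> int:
    """Observed richness: number of taxa with non-zero abundance."""
    return int(np.count_nonzero(np.asarray(row)))


def chao1(row: np.ndarray | pd.Series) -> float:
    """Chao1 richness estimate from a single count row.

    ``S_obs + F1^2 / (2 F2)`` with singletons F1 and doubletons F2; the
    bias-corrected form ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` is used when
    there are no doubletons.  An all-zero row estimates 0.
    """
    row = np.asarray(row)
    s_obs = richness(row)
    if s_obs == 0:
        return 0.0
    f1 = int(np.sum(row == 1))
    f2 = int(np.sum(row == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def aggregate_taxa(matrix: pd.DataFrame, taxonomy: pd.DataFrame,
                   level: str = "phylum", policy: str = "error") -> pd.DataFrame:
    """Sum taxon columns into higher-rank groups.

    At ``level='phylum'`` Proteobacteria are reported at class rank
    (Alphaproteobacteria, Gammaproteobacteria, ...) instead of as one phylum,
    mirroring the convention of splitting that phylum because of its breadth.
    Per-sample totals are conserved exactly.  Taxa missing from the taxonomy
    raise by default, or are dropped when ``policy='drop'``.
    """
    tax = taxonomy.set_index("taxon_id")
    missing = [t for t in matrix.columns if t not in tax.index]
    if missing:
        if policy != "drop":
            raise KeyError(f"taxa without taxonomy entries: {missing}")
        log.warning("aggregate_taxa: dropping %d taxa without taxonomy", len(missing))
    cols = [t for t in matrix.columns if t in tax.index]

    def group_of(t: str) -> str:
        phylum = tax.at[t, "phylum"]
        if level == "phylum" and phylum == "Proteobacteria":
            cls = tax.at[t, "class"] if "class" in tax.columns else ""
            if isinstance(cls, str) and cls:
                return cls
        if level not in tax.columns and level != "phylum":
            raise KeyError(f"taxonomy has no rank '{level}'")
        return tax.at[t, level] if level != "phylum" else phylum

    groups = {t: group_of(t) for t in cols}
    return matrix[cols].T.groupby(groups).sum().T


def prevalence_filter(matrix: pd.DataFrame, min_frac: float = 0.0,
                      max_frac: float = 1.0) -> pd.DataFrame:
    """Keep taxa whose occupancy fraction lies in ``[min_frac, max_frac]``.

    Boundaries are inclusive: with 10 samples and ``min_frac=0.8`` a taxon
    present in exactly 8 samples is kept.
    """
    if not (0.0 <= min_frac <= max_frac <= 1.0):
        raise ValueError("need 0 <= min_frac <= max_frac <= 1")
    occ = (matrix > 0).mean(axis=0)
    keep = (occ >= min_frac) & (occ <= max_frac)
    if not keep.any():
        log.warning("prevalence_filter: no taxa retained")
    return matrix.loc[:, keep]


@dataclass
class MultidiversityResult:
    md: pd.Series
    components: list[str]
    mode: str


def multidiversity(richness_table: pd.DataFrame,
                   mode: str = "zscore") -> MultidiversityResult:
    """Multidiversity: per-sample mean of standardized richness components.

    Components are the richness of plants, of the whole bacterial community,
    and of each dominant bacterial phylum; each column is standardized
    (Z-score by default, max-scaling optionally) and averaged per sample.
    Zero-variance components are dropped with a warning.
    """
    if len(richness_table) < 2:
        raise ValueError("multidiversity needs at least 2 samples")
    table = richness_table.astype(float)
    sd = table.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        log.warning("multidiversity: dropping constant component(s) %s", constant)
        table = table.drop(columns=constant)
    if table.shape[1] == 0:
        raise ValueError("all multidiversity components are constant")
    if mode == "zscore":
        std = (table - table.mean()) / table.std(ddof=1)
    elif mode == "max-scale":
        std = table / table.max()
    else:
        raise ValueError(f"unknown standardization mode {mode!r}")
    return MultidiversityResult(md=std.mean(axis=1), components=list(table.columns), mode=mode)


def importance_value(density: np.ndarray, coverage: np.ndarray,
                     height: np.ndarray) -> np.ndarray:
    """Importance value of each species within one plot.

    The mean of a species' relative density, relative coverage and relative
    height; sums to 1 over the plot's species when all three plot totals are
    positive.  A zero plot total contributes zero shares for that attribute
    while the averaging divisor stays 3.
    """
    parts = []
    for attr in (np.asarray(density, float), np.asarray(coverage, float),
                 np.asarray(height, float)):
        if (attr < 0).any():
            raise ValueError("plant attributes must be non-negative")
        total = attr.sum()
        parts.append(attr / total if total > 0 else np.zeros_like(attr))
    return sum(parts) / 3.0


# Allometric coefficients from regional forestry equations; volume index
# V = 100 * height(m) * coverage(fraction).
def plant_biomass(plant_type: str, height: float, coverage: float) -> float:
    """Plot-level plant biomass from height and coverage, by plant type.

    fir:      (0.4642 V + 47.4990) / 100
    hardwood: (0.6573 V^1.0502) / 100
    softwood: (2.1529 V^0.6085) / 100
    shrub:    (0.0398 * height*100 - 0.3326) * coverage / 25
    herb:     (0.0175 * height*100 - 0.2888) * coverage

    The shrub/herb equations can go negative for very small plants; negative
    outputs are clipped to 0 with a warning.
    """
    if height < 0 or coverage < 0:
        raise ValueError("height and coverage must be non-negative")
    v = 100.0 * height * coverage
    if plant_type == "fir":
        out = (0.4642 * v + 47.4990) / 100.0
    elif plant_type == "hardwood":
        out = (0.6573 * v ** 1.0502) / 100.0
    elif plant_type == "softwood":
        out = (2.1529 * v ** 0.6085) / 100.0
    elif plant_type == "shrub":
        out = (0.0398 * height * 100.0 - 0.3326) * coverage / 25.0
    elif plant_type == "herb":
        out = (0.0175 * height * 100.0 - 0.2888) * coverage
    else:
        raise ValueError(f"unknown plant type {plant_type!r}")
    if out < 0:
        log.warning("plant_biomass: negative %s biomass clipped to 0", plant_type)
        return 0.0
    return float(out)
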