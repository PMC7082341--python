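"""End-to-end analysis pipeline and table IO.

``run_pipeline`` chains the stages on a dataset directory (or an in-memory
bundle): diversity -> ordination -> breakpoints -> multifunctionality ->
drivers, writing TSV/JSON results plus a machine-readable ``summary.json``.
All randomized stages draw seeds deterministically from ``RunConfig.seed``,
so one config gives byte-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, composition, breakpoints as bp, multifunc, drivers
from .simulate import SyntheticBundle, FUNCTION_NAMES, FUNCTION_GROUPS, _MINERALS, _METALS

__all__ = ["RunConfig", "read_tables", "run_pipeline"]

log = logging.getLogger(__name__)

REQUIRED_FILES = ("samples.tsv", "plant_matrix.tsv", "otu_matrix.tsv",
                  "taxonomy.tsv", "plant_attributes.tsv")


@dataclass
class RunConfig:
    """Knobs of the full pipeline run."""

    band: tuple[float, float] = (1800.0, 3000.0)
    rarefaction_depth: int = 10_000
    n_perm: int = 199
    n_boot: int = 199
    subset_perm: int = 200
    dominant_prevalence: float = 0.8
    seed: int = 0
    data_dir: str | None = None
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_perm < 99 or self.n_boot < 99 or self.subset_perm < 99:
            raise ValueError("permutation/bootstrap counts must be >= 99")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction depth must be >= 1")

    def analysis_params(self) -> dict:
        """Config fields that affect results (file locations excluded)."""
        d = asdict(self)
        d.pop("data_dir", None)
        d.pop("out_dir", None)
        return d

    def digest(self) -> str:
        payload = json.dumps(self.analysis_params(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_tables(path: str | Path) -> SyntheticBundle:
    """Read a dataset directory, reporting *all* validation problems at once.

    Expects the canonical TSV layout (``samples.tsv``, ``plant_matrix.tsv``,
    ``otu_matrix.tsv``, ``taxonomy.tsv``, ``plant_attributes.tsv`` and an
    optional ``truth.json``).  Cross-file sample-key mismatches and missing
    columns are aggregated into a single error.
    """
    path = Path(path)
    problems: list[str] = []
    for name in REQUIRED_FILES:
        if not (path / name).exists():
            problems.append(f"missing file: {name}")
    if problems:
        raise FileNotFoundError("; ".join(problems))

    bundle = SyntheticBundle.from_dir(path) if (path / "truth.json").exists() else \
        SyntheticBundle(
            sample_frame=pd.read_csv(path / "samples.tsv", sep="\t", index_col=0),
            plant_matrix=pd.read_csv(path / "plant_matrix.tsv", sep="\t", index_col=0),
            otu_matrix=pd.read_csv(path / "otu_matrix.tsv", sep="\t", index_col=0),
            plant_attributes=pd.read_csv(path / "plant_attributes.tsv", sep="\t"),
            taxonomy=pd.read_csv(path / "taxonomy.tsv", sep="\t"),
            truth={},
        )

    samples = set(bundle.sample_frame.index)
    for name, idx in (("plant_matrix", bundle.plant_matrix.index),
                      ("otu_matrix", bundle.otu_matrix.index)):
        extra = set(idx) - samples
        absent = samples - set(idx)
        if extra:
            problems.append(f"{name}: samples not in metadata: {sorted(extra)[:5]}")
        if absent:
            problems.append(f"{name}: metadata samples missing: {sorted(absent)[:5]}")
    for col in ("site_id", "elevation"):
        if col not in bundle.sample_frame.columns:
            problems.append(f"samples.tsv: missing column {col!r}")
    if "taxon_id" not in bundle.taxonomy.columns:
        problems.append("taxonomy.tsv: missing column 'taxon_id'")
    if problems:
        raise ValueError("dataset validation failed: " + "; ".join(problems))
    return bundle


def _derived_seed(base: int, label: str) -> int:
    h = hashlib.sha256(f"{base}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig, bundle: SyntheticBundle | None = None) -> dict:
    """Run the full elevational analysis; returns the summary dict.

    Stages: rarefaction and diversity (richness, multidiversity), ordination
    (DCA of communities and functions, PCA of minerals/metals), breakpoints
    (piecewise fits per facet with bootstrap CIs, adjacent-site turnover,
    split density, consensus summaries), multifunctionality (EMF, group EMF,
    subset curve), and driver attribution (model averaging, geological
    increment, variation partitioning, composite path model).  Outputs land
    in ``config.out_dir``; every table carries the config hash in its name
    metadata and the summary records every derived seed.
    """
    if bundle is None:
        if config.data_dir is None:
            raise ValueError("either a bundle or config.data_dir is required")
        bundle = read_tables(config.data_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.digest()
    seeds = {stage: _derived_seed(config.seed, stage)
             for stage in ("rarefy", "turnover_otu", "turnover_plant",
                           "boot", "subset", "drivers")}
    summary: dict = {"config": _round_floats(config.analysis_params()),
                     "config_hash": cfg_hash, "derived_seeds": seeds}
    sf = bundle.sample_frame
    elev = sf["elevation"].to_numpy(dtype=float)
    site = sf["site_id"]
    site_elev = sf.groupby("site_id")["elevation"].mean()
    spacing = float(np.diff(np.sort(site_elev.unique())).mean())

    # --- diversity -----------------------------------------------------------
    log.info("stage=diversity hash=%s", cfg_hash)
    otu = community.rarefy(bundle.otu_matrix, config.rarefaction_depth,
                           seed=seeds["rarefy"])
    phyla = community.aggregate_taxa(otu, bundle.taxonomy, level="phylum")
    dominant = community.prevalence_filter(phyla, min_frac=config.dominant_prevalence)
    rich = pd.DataFrame(index=otu.index)
    rich["bacteria"] = [community.richness(r) for r in otu.to_numpy()]
    rich["plants"] = [community.richness(r) for r in
                      bundle.plant_matrix.loc[otu.index].to_numpy()]
    phylum_map = _phylum_map(bundle.taxonomy)
    per_phylum = pd.DataFrame(
        {f"phylum:{p}": [community.richness(r) for r in
                         otu[[t for t in otu.columns
                              if phylum_map.get(t) == p]].to_numpy()]
         for p in dominant.columns}, index=otu.index)
    md_result = community.multidiversity(pd.concat([rich, per_phylum], axis=1))
    md = md_result.md

    # --- ordination ----------------------------------------------------------
    log.info("stage=ordination hash=%s", cfg_hash)
    dca_bact = composition.dca(otu)
    dca_plant = composition.dca(bundle.plant_matrix.loc[otu.index])
    fun_table = sf.loc[otu.index, list(FUNCTION_NAMES)]
    fun01 = (fun_table - fun_table.min()) / (fun_table.max() - fun_table.min())
    dca_fun = composition.dca(fun01)
    pca_minerals = composition.pca(sf.loc[otu.index, list(_MINERALS)], scale=True)
    pca_metals = composition.pca(sf.loc[otu.index, list(_METALS)], scale=True)

    # --- multifunctionality --------------------------------------------------
    log.info("stage=multifunctionality hash=%s", cfg_hash)
    z = multifunc.zscore_table(fun_table)
    emf = multifunc.emf(z)
    gemf = multifunc.group_emf(z, FUNCTION_GROUPS)
    curve = multifunc.emf_subset_curve(z, k_min=10, n_perm=config.subset_perm,
                                       seed=seeds["subset"])
    emf_out = pd.concat([z, emf.rename("EMF"), gemf.add_prefix("EMF:")], axis=1)
    emf_out.to_csv(out / "emf_table.tsv", sep="\t")
    curve.table.to_csv(out / "emf_subset_curve.tsv", sep="\t", index=False)

    # --- breakpoints ---------------------------------------------------------
    log.info("stage=breakpoints hash=%s", cfg_hash)
    x = sf.loc[otu.index, "elevation"].to_numpy(dtype=float)
    facets: dict[str, list[bp.BreakpointFit]] = {"function": [], "emf": [],
                                                 "diversity": [], "composition": []}
    fit_rows = []

    def add_fit(facet: str, name: str, y: pd.Series, n_boot: int) -> bp.BreakpointFit:
        fit = bp.piecewise_fit(x, y.to_numpy(dtype=float), band=config.band,
                               n_boot=n_boot,
                               seed=_derived_seed(seeds["boot"], name))
        facets[facet].append(fit)
        fit_rows.append({"facet": facet, "response": name, "psi": fit.psi,
                         "beta1": fit.beta1, "beta2": fit.beta2, "r2": fit.r2,
                         "p_improvement": fit.p_improvement,
                         "ci_low": fit.ci_low, "ci_high": fit.ci_high,
                         "edge_limited": fit.edge_limited})
        return fit

    for name in FUNCTION_NAMES:
        add_fit("function", name, fun_table[name], n_boot=0)
    emf_fit = add_fit("emf", "EMF", emf, n_boot=config.n_boot)
    for gname in gemf.columns:
        add_fit("emf", f"EMF:{gname}", gemf[gname], n_boot=0)
    add_fit("diversity", "multidiversity", md, n_boot=config.n_boot)
    add_fit("diversity", "bacteria_richness", rich["bacteria"], n_boot=0)
    add_fit("diversity", "plant_richness", rich["plants"], n_boot=0)
    add_fit("composition", "bacteria_DCA1", dca_bact.scores["DCA1"], n_boot=0)
    add_fit("composition", "plant_DCA1", dca_plant.scores["DCA1"], n_boot=0)
    add_fit("composition", "function_DCA1", dca_fun.scores["DCA1"], n_boot=0)
    pd.DataFrame(fit_rows).to_csv(out / "breakpoint_fits.tsv", sep="\t", index=False)

    turnover = bp.adjacent_turnover(otu, site.loc[otu.index], site_elev,
                                    band=config.band, n_perm=config.n_perm,
                                    seed=seeds["turnover_otu"])
    turnover.table.to_csv(out / "turnover_profile.tsv", sep="\t", index=False)
    density = bp.split_density(otu, x)
    pd.DataFrame({"elevation": density.grid,
                  "raw_density": density.raw_density,
                  "data_density": density.data_density,
                  "standardized": density.standardized}).to_csv(
        out / "split_density.tsv", sep="\t", index=False)
    consensus = bp.consensus_breakpoints(facets)
    consensus.to_csv(out / "consensus_breakpoints.tsv", sep="\t")

    # --- drivers -------------------------------------------------------------
    log.info("stage=drivers hash=%s", cfg_hash)
    geochem = drivers.geochem_indices(sf.loc[otu.index])
    contemporary = pd.DataFrame({
        "mat": sf.loc[otu.index, "mat"], "map": sf.loc[otu.index, "map"],
        "ph": sf.loc[otu.index, "ph"], "moisture": sf.loc[otu.index, "moisture"],
        "plant_dca1": dca_plant.scores["DCA1"].reindex(otu.index),
    }).dropna(axis=1, how="any")
    geological = pd.DataFrame({
        "minerals_pc1": pca_minerals.scores["PC1"],
        "minerals_pc2": pca_minerals.scores["PC2"],
        "metals_pc1": pca_metals.scores["PC1"],
        "cia": geochem["cia"], "ca_al": geochem["ca_al"],
        "mg_al": geochem["mg_al"], "ti_fe": geochem["ti_fe"],
    }).dropna(axis=1, how="any")

    driver_summary = {}
    for rname, resp in (("MD", md), ("EMF", emf)):
        contemp_d, log_c = drivers.dereplicate_predictors(contemporary, resp)
        geo_d, log_g = drivers.dereplicate_predictors(geological, resp)
        avg = drivers.all_subsets_average(resp, pd.concat([contemp_d, geo_d], axis=1))
        inc = drivers.geo_increment(resp, contemp_d, geo_d)
        vpa = drivers.variation_partition(resp, contemp_d, geo_d)
        comp, edges, pdata = _composite_path_inputs(resp, rname, contemporary,
                                                    geological, geochem,
                                                    pca_minerals, dca_plant, otu.index)
        path = drivers.path_fit(pdata, edges, outcome=rname)
        avg.beta.to_frame().join(avg.importance).to_csv(
            out / f"model_average_{rname}.tsv", sep="\t")
        driver_summary[rname] = {
            "averaged_beta": avg.beta.round(6).to_dict(),
            "importance": avg.importance.round(6).to_dict(),
            "dereplication": {"contemporary": log_c, "geological": log_g},
            "geo_increment": {
                "r2_contemporary": inc.r2_contemporary,
                "r2_with_geology": inc.r2_with_geology,
                "percent_increase": inc.percent_increase,
                "p_value": inc.p_value,
                "significant_fraction": inc.significant_fraction,
            },
            "variance_partition": {"a_contemporary": vpa.a, "b_geological": vpa.b,
                                   "c_shared": vpa.c, "d_residual": vpa.d},
            "path": {"edges": [list(e) for e in path.edges],
                     "coefficients": {f"{a}->{b}": round(v, 6)
                                      for (a, b), v in path.coefficients.items()},
                     "direct": path.direct, "indirect": path.indirect,
                     "total": path.total, "srmr": path.srmr, "r2": path.r2},
        }

    # --- summary -------------------------------------------------------------
    summary.update({
        "site_spacing_m": spacing,
        "n_samples": int(len(otu)),
        "consensus_breakpoints": consensus.reset_index().to_dict(orient="records"),
        "emf_breakpoint": {"psi": emf_fit.psi, "ci_low": emf_fit.ci_low,
                           "ci_high": emf_fit.ci_high,
                           "p_improvement": emf_fit.p_improvement},
        "turnover_breakpoint_elev": turnover.breakpoint_elev,
        "split_density_peak_elev": density.peak_elev,
        "pca_minerals_percent_first2": float(pca_minerals.percent_explained[:2].sum()),
        "pca_metals_percent_first2": float(pca_metals.percent_explained[:2].sum()),
        "emf_mean": float(emf.mean()),
        "emf_subset_correlation_by_k": {int(k): round(float(v), 6)
                                        for k, v in curve.correlation.items()},
        "drivers": driver_summary,
    })
    if bundle.truth:
        summary["truth_fault_elev"] = bundle.truth.get("fault_elev")
    summary = _round_floats(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    log.info("pipeline complete: %s", out / "summary.json")
    return summary


def _phylum_map(taxonomy: pd.DataFrame) -> dict[str, str]:
    """Taxon -> reporting group (phylum, with Proteobacteria at class rank)."""
    out = {}
    has_class = "class" in taxonomy.columns
    for _, row in taxonomy.iterrows():
        group = row["phylum"]
        if group == "Proteobacteria" and has_class:
            cls = row["class"]
            if isinstance(cls, str) and cls:
                group = cls
        out[row["taxon_id"]] = group
    return out


def _composite_path_inputs(resp: pd.Series, rname: str, contemporary: pd.DataFrame,
                           geological: pd.DataFrame, geochem: pd.DataFrame,
                           pca_minerals, dca_plant, index):
    """Composite variables and the hypothesized DAG for the path model."""
    composites = {}
    for name, cols, source in (
        ("climate", ["mat", "map"], contemporary),
        ("local", ["ph", "moisture"], contemporary),
        ("parent_rock", ["minerals_pc1", "minerals_pc2"], geological),
        ("weathering", ["cia", "ca_al", "mg_al", "ti_fe"], geological),
    ):
        cols = [c for c in cols if c in source.columns]
        comp, _ = drivers.composite_score(source[cols], resp)
        composites[name] = comp
    biotic = dca_plant.scores["DCA1"].reindex(index)
    data = pd.DataFrame(composites, index=index)
    data["biotic"] = biotic
    data[rname] = resp
    edges = [("parent_rock", "weathering"),
             ("climate", "local"), ("weathering", "local"),
             ("climate", "biotic"), ("weathering", "biotic"), ("local", "biotic"),
             ("climate", rname), ("weathering", rname),
             ("local", rname), ("biotic", rname)]
    return composites, edges, data
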