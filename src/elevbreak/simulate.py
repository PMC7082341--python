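"""Seeded synthetic elevational-gradient datasets with planted ground truth.

The generator emulates a montane soil survey: sites laid out along a
700-3760 m gradient (18 sites x 10 plots by default), a tectonic fault at a
configurable elevation inside the 1800-3000 m band, Gaussian-niche (coenocline)
taxon responses with below-/above-fault species pools, geological variables
that step across the fault, a linear temperature lapse, and 38 ecosystem
function columns with piecewise-linear elevational responses.  Every planted
parameter is recorded in ``SyntheticBundle.truth`` so downstream breakpoint,
multifunctionality and driver analyses can be scored against known answers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "SyntheticBundle",
    "gaussian_niche",
    "simulate_mountain",
    "simulate_two_mountains",
    "FUNCTION_GROUPS",
]

PLANT_TYPES = ("fir", "hardwood", "softwood", "shrub", "herb")

_PHYLA = (
    "Acidobacteria",
    "Actinobacteria",
    "Bacteroidetes",
    "Chloroflexi",
    "Cyanobacteria",
    "Firmicutes",
    "Gemmatimonadetes",
    "Nitrospirae",
    "Planctomycetes",
    "Verrucomicrobia",
    "Proteobacteria",
)
_PROTEO_CLASSES = (
    "Alphaproteobacteria",
    "Betaproteobacteria",
    "Gammaproteobacteria",
    "Deltaproteobacteria",
)

# 38 ecosystem functions in the five conventional functional groups.
FUNCTION_GROUPS: dict[str, str] = {}
for _name in (
    "fir_biomass", "hardwood_biomass", "softwood_biomass", "shrub_biomass",
    "herb_biomass", "tree_density", "shrub_density", "herb_density",
    "tree_height", "shrub_height", "herb_height", "tree_coverage",
    "shrub_coverage", "herb_coverage",
):
    FUNCTION_GROUPS[_name] = "plant_biomass"
for _name in (
    "plfa_bacteria", "plfa_fungi", "plfa_actinomycetes", "plfa_protozoa",
    "bgdgt", "igdgt", "gdgt0", "crenarchaeol",
):
    FUNCTION_GROUPS[_name] = "microbial_biomass"
for _name in (
    "beta_glucosidase", "amylase", "invertase", "phenol_oxidase", "cellulase",
):
    FUNCTION_GROUPS[_name] = "enzyme_activity"
for _name in (
    "cyanobacteria_ra", "rhodospirillales_ra", "rhodocyclales_ra", "chlorobi_ra",
):
    FUNCTION_GROUPS[_name] = "photosynthetic_bacteria"
for _name in ("toc", "tn", "tp", "wsoc", "wson", "nh4_n", "no3_n"):
    FUNCTION_GROUPS[_name] = "soil_nutrients"

FUNCTION_NAMES = tuple(FUNCTION_GROUPS)
assert len(FUNCTION_NAMES) == 38

_MINERALS = ("quartz", "plagioclase", "k_feldspar", "amphibole", "muscovite", "chlorite")
_METALS = ("ca", "fe", "mg", "al", "k", "na", "mn", "ti")
_OXIDES = ("al2o3", "cao_star", "na2o", "k2o")


@dataclass
class SimulationParams:
    """Knobs of the synthetic mountain.

    Elevations are metres above sea level; the fault elevation must sit
    strictly inside the sampled gradient (and, by survey design, inside the
    1800-3000 m candidate band).  ``pool_mixing`` is the abruptness kappa of
    species-pool replacement at the fault: a taxon's expected abundance on the
    "wrong" side of the fault is multiplied by ``1 - kappa``, so ``kappa=0``
    yields a smooth coenocline and ``kappa=1`` a hard replacement.
    """

    n_sites: int = 18
    plots_per_site: int = 10
    elev_min: float = 700.0
    elev_max: float = 3760.0
    fault_elev: float = 2400.0
    pool_mixing: float = 0.9
    n_plant_species: int = 40
    n_otus: int = 300
    niche_tolerance: float = 350.0       # mean sigma_s (m)
    max_abundance: float = 10.0          # mean A_s
    mat_intercept: float = 24.0          # deg C at sea level
    mat_lapse: float = 0.0055            # deg C per m
    geo_step: float = 1.0                # fault step in within-column SD units
    sequencing_depth: int = 10_000
    noise_sd: dict[str, float] = field(default_factory=lambda: {
        "mat": 0.5, "env": 0.3, "geo": 0.3, "function": 0.5,
    })
    site_elevations: Sequence[float] | None = None
    break_fraction: float = 0.6          # fraction of functions with a planted slope change
    # planted driver structure: habitat suitability of "sensitive" taxa responds
    # to the realized weathering index (direct geology -> diversity) and to MAT
    diversity_effect_weathering: float = 1.5
    diversity_effect_mat: float = 0.5
    sensitive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.elev_min < self.fault_elev < self.elev_max):
            raise ValueError("fault_elev must lie strictly inside [elev_min, elev_max]")
        if not (0.0 <= self.pool_mixing <= 1.0):
            raise ValueError("pool_mixing must lie in [0, 1]")
        if self.niche_tolerance <= 0:
            raise ValueError("niche_tolerance must be positive")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")
        if self.n_sites < 2 or self.plots_per_site < 1:
            raise ValueError("need at least 2 sites and 1 plot per site")

    def elevations(self) -> np.ndarray:
        """Site elevations: evenly spaced by default, or the explicit override."""
        if self.site_elevations is not None:
            elev = np.asarray(self.site_elevations, dtype=float)
            if len(elev) != self.n_sites:
                raise ValueError("site_elevations length must equal n_sites")
            return elev
        return np.linspace(self.elev_min, self.elev_max, self.n_sites)


@dataclass
class SyntheticBundle:
    """One simulated mountain: plot-level tables plus the planted truth."""

    sample_frame: pd.DataFrame
    plant_matrix: pd.DataFrame
    otu_matrix: pd.DataFrame
    plant_attributes: pd.DataFrame
    taxonomy: pd.DataFrame
    truth: dict

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.sample_frame.to_csv(path / "samples.tsv", sep="\t")
        self.plant_matrix.to_csv(path / "plant_matrix.tsv", sep="\t")
        self.otu_matrix.to_csv(path / "otu_matrix.tsv", sep="\t")
        self.plant_attributes.to_csv(path / "plant_attributes.tsv", sep="\t", index=False)
        self.taxonomy.to_csv(path / "taxonomy.tsv", sep="\t", index=False)
        (path / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "SyntheticBundle":
        path = Path(path)
        return cls(
            sample_frame=pd.read_csv(path / "samples.tsv", sep="\t", index_col=0),
            plant_matrix=pd.read_csv(path / "plant_matrix.tsv", sep="\t", index_col=0),
            otu_matrix=pd.read_csv(path / "otu_matrix.tsv", sep="\t", index_col=0),
            plant_attributes=pd.read_csv(path / "plant_attributes.tsv", sep="\t"),
            taxonomy=pd.read_csv(path / "taxonomy.tsv", sep="\t"),
            truth=json.loads((path / "truth.json").read_text()),
        )


def gaussian_niche(
    elevation: np.ndarray | float,
    optimum: np.ndarray | float,
    tolerance: np.ndarray | float,
    peak: np.ndarray | float = 1.0,
) -> np.ndarray | float:
    """Expected abundance of a taxon with a Gaussian (coenocline) niche.

    ``peak * exp(-(elevation - optimum)^2 / (2 tolerance^2))`` — the standard
    unimodal response model; maximal at the optimum, symmetric around it.
    """
    tolerance = np.asarray(tolerance, dtype=float)
    if np.any(tolerance <= 0):
        raise ValueError("niche tolerance (sigma) must be positive")
    elevation = np.asarray(elevation, dtype=float)
    z = (elevation - optimum) / tolerance
    out = peak * np.exp(-0.5 * z * z)
    return out if out.ndim else float(out)


def _draw_taxa(params: SimulationParams, rng: np.random.Generator, n: int) -> dict:
    """Niche parameters and fault-pool membership for ``n`` taxa.

    Taxa are split evenly into a below-fault and an above-fault pool; optima
    are drawn uniformly on the pool's side of the fault (with a margin so
    edge sites are occupied too).
    """
    pool = rng.random(n) < 0.5  # True = above-fault pool
    margin = 200.0
    lo = rng.uniform(params.elev_min - margin, params.fault_elev, size=n)
    hi = rng.uniform(params.fault_elev, params.elev_max + margin, size=n)
    mu = np.where(pool, hi, lo)
    sigma = params.niche_tolerance * rng.lognormal(0.0, 0.3, size=n)
    peak = params.max_abundance * rng.lognormal(0.0, 0.5, size=n)
    return {"pool_above": pool, "mu": mu, "sigma": sigma, "peak": peak}


def _expected_abundance(elev: np.ndarray, taxa: dict, fault: float, kappa: float) -> np.ndarray:
    """Samples x taxa expected abundances with fault-pool suppression."""
    f = gaussian_niche(elev[:, None], taxa["mu"][None, :], taxa["sigma"][None, :],
                       taxa["peak"][None, :])
    above = elev[:, None] > fault
    wrong_side = above != taxa["pool_above"][None, :]
    return np.asarray(f) * np.where(wrong_side, 1.0 - kappa, 1.0)


def _function_coefficients(params: SimulationParams, rng: np.random.Generator) -> dict:
    """Per-function linear / piecewise-linear coefficients (elevation in km)."""
    k = len(FUNCTION_NAMES)
    c0 = rng.normal(0.0, 1.0, size=k)
    c1 = rng.normal(0.0, 1.0, size=k)
    has_break = rng.random(k) < params.break_fraction
    c2 = np.where(has_break, rng.choice([-1.0, 1.0], size=k) * rng.uniform(4.0, 6.0, size=k), 0.0)
    return {"c0": c0, "c1": c1, "c2": c2,
            "c_mat": rng.normal(0.0, 0.8, size=k),
            "c_moist": rng.normal(0.0, 0.4, size=k),
            "c_bio": rng.normal(0.0, 0.2, size=k),
            "c_div": rng.normal(0.0, 0.15, size=k)}


def simulate_mountain(params: SimulationParams | None = None, *,
                      mountain: str = "A",
                      _seed_sequences: list | None = None) -> SyntheticBundle:
    """Simulate one mountain transect with a planted fault.

    Returns a :class:`SyntheticBundle` whose ``truth`` block records the fault
    elevation, every niche parameter, the temperature lapse, the geological
    step signs and the function coefficients.  Identical parameters and seed
    give a bit-identical bundle.
    """
    params = params or SimulationParams()
    if _seed_sequences is None:
        _seed_sequences = np.random.SeedSequence(params.seed).spawn(6)
    (rng_taxa, rng_counts, rng_plants, rng_geo, rng_env, rng_fun) = (
        np.random.default_rng(s) for s in _seed_sequences)

    site_elev = params.elevations()
    n = params.n_sites * params.plots_per_site
    site_ids = np.repeat([f"S{i + 1:02d}" for i in range(params.n_sites)], params.plots_per_site)
    elev = np.repeat(site_elev, params.plots_per_site)
    sample_ids = [f"{mountain}.{s}.P{p + 1:02d}"
                  for s in [f"S{i + 1:02d}" for i in range(params.n_sites)]
                  for p in range(params.plots_per_site)]
    # --- environment ---------------------------------------------------------
    noise = params.noise_sd
    mat = (params.mat_intercept - params.mat_lapse * elev
           + rng_env.normal(0, noise["mat"], n))
    env = pd.DataFrame(index=sample_ids)
    env["site_id"] = site_ids
    env["elevation"] = elev
    env["mountain"] = mountain
    env["mat"] = mat
    env["map"] = 2200.0 - 0.3 * elev + rng_env.normal(0, 40 * noise["env"] / 0.3, n)
    env["ph"] = 6.8 - 0.0005 * elev + rng_env.normal(0, noise["env"] * 0.5, n)
    env["moisture"] = np.clip(0.15 + 0.00008 * elev + rng_env.normal(0, noise["env"] * 0.05, n),
                              0.01, 0.95)

    # --- geology: columns step across the fault ------------------------------
    above = (elev > params.fault_elev).astype(float)
    geo_cols = list(_MINERALS) + list(_METALS)
    base = {"quartz": 30, "plagioclase": 20, "k_feldspar": 10, "amphibole": 5,
            "muscovite": 8, "chlorite": 6,
            "ca": 3.0, "fe": 4.0, "mg": 2.0, "al": 8.0, "k": 2.5, "na": 1.5,
            "mn": 0.1, "ti": 0.5}
    step_sign = {c: int(s) for c, s in zip(geo_cols, rng_geo.choice([-1, 1], size=len(geo_cols)))}
    for c in geo_cols:
        scale = base[c] * 0.15
        env[c] = (base[c] + step_sign[c] * params.geo_step * scale * above
                  + rng_geo.normal(0, noise["geo"] * scale, n))
        env[c] = env[c].clip(lower=0.01)
    # molar oxide proportions for the weathering index; Al2O3 steps at the fault
    oxide_base = {"al2o3": 45.0, "cao_star": 20.0, "na2o": 18.0, "k2o": 17.0}
    for c in _OXIDES:
        sgn = 1 if c == "al2o3" else -0.3
        env[c] = np.clip(oxide_base[c] + sgn * params.geo_step * 4.0 * above
                         + rng_geo.normal(0, noise["geo"] * 2.0, n), 0.5, None)

    # planted driver structure: habitat suitability of "sensitive" taxa tracks
    # the realized weathering index (CIA) and MAT, so geology has a direct
    # effect on diversity and, via diversity, an indirect effect on functions
    cia = 100.0 * env["al2o3"] / (env["al2o3"] + env["cao_star"] + env["na2o"] + env["k2o"])
    weathering_z = ((cia - cia.mean()) / cia.std(ddof=1)).to_numpy()
    mat_z = (mat - mat.mean()) / mat.std(ddof=1)
    eta = (params.diversity_effect_weathering * weathering_z
           + params.diversity_effect_mat * mat_z)
    # suitability acts on occupancy: a sensitive taxon occupies a plot with
    # probability logistic(0.5 + eta), so richness responds to the drivers
    occupancy_p = 1.0 / (1.0 + np.exp(-(0.5 + eta)))

    # --- bacterial community -------------------------------------------------
    otus = _draw_taxa(params, rng_taxa, params.n_otus)
    otus["sensitive"] = rng_taxa.random(params.n_otus) < params.sensitive_fraction
    expected = _expected_abundance(elev, otus, params.fault_elev, params.pool_mixing)
    n_sens = int(otus["sensitive"].sum())
    expected[:, otus["sensitive"]] *= (
        rng_counts.random((n, n_sens)) < occupancy_p[:, None])
    rel = expected + 1e-12  # guard against empty rows at extreme parameters
    rel = rel / rel.sum(axis=1, keepdims=True)
    counts = np.vstack([rng_counts.multinomial(params.sequencing_depth, p) for p in rel])
    otu_ids = [f"OTU{i + 1:04d}" for i in range(params.n_otus)]
    otu_matrix = pd.DataFrame(counts, index=sample_ids, columns=otu_ids)

    phyla = rng_taxa.choice(len(_PHYLA), size=params.n_otus)
    proteo_class = rng_taxa.choice(_PROTEO_CLASSES, size=params.n_otus)
    taxonomy = pd.DataFrame({
        "taxon_id": otu_ids,
        "phylum": [_PHYLA[i] for i in phyla],
        "class": [proteo_class[j] if _PHYLA[i] == "Proteobacteria" else ""
                  for j, i in enumerate(phyla)],
    })

    # --- plant community and attributes -------------------------------------
    plants = _draw_taxa(params, rng_taxa, params.n_plant_species)
    plants["sensitive"] = rng_taxa.random(params.n_plant_species) < params.sensitive_fraction
    plant_expected = _expected_abundance(elev, plants, params.fault_elev, params.pool_mixing)
    n_sens_p = int(plants["sensitive"].sum())
    plant_expected[:, plants["sensitive"]] *= (
        rng_plants.random((n, n_sens_p)) < occupancy_p[:, None])
    plant_counts = rng_plants.poisson(plant_expected)
    plant_ids = [f"PL{i + 1:03d}" for i in range(params.n_plant_species)]
    plant_matrix = pd.DataFrame(plant_counts, index=sample_ids, columns=plant_ids)
    plant_type = rng_taxa.choice(PLANT_TYPES, size=params.n_plant_species,
                                 p=[0.1, 0.15, 0.1, 0.3, 0.35])

    rows = []
    type_height = {"fir": 18.0, "hardwood": 14.0, "softwood": 12.0, "shrub": 1.5, "herb": 0.3}
    for i, sid in enumerate(sample_ids):
        present = np.flatnonzero(plant_counts[i])
        for j in present:
            t = plant_type[j]
            rows.append({
                "sample_id": sid,
                "species": plant_ids[j],
                "type": t,
                "density": int(plant_counts[i, j]),
                "coverage": float(np.clip(rng_plants.beta(2, 5) * plant_counts[i, j] / 10, 0, 1)),
                "height": float(type_height[t] * rng_plants.lognormal(0, 0.25)),
            })
    plant_attributes = pd.DataFrame(
        rows, columns=["sample_id", "species", "type", "density", "coverage", "height"])

    # --- ecosystem functions --------------------------------------------------
    # linear / piecewise-linear in elevation plus contributions from realized
    # MAT, moisture, plant biomass and the diversity driver (so weathering
    # reaches functions only indirectly, through diversity)
    coef = _function_coefficients(params, rng_fun)
    z = elev / 1000.0
    zpsi = params.fault_elev / 1000.0
    biomass_proxy = plant_counts.sum(axis=1).astype(float)
    biomass_z = (biomass_proxy - biomass_proxy.mean()) / biomass_proxy.std(ddof=1)
    moist_z = ((env["moisture"] - env["moisture"].mean())
               / env["moisture"].std(ddof=1)).to_numpy()
    fun = (coef["c0"][None, :] + coef["c1"][None, :] * z[:, None]
           + coef["c2"][None, :] * np.clip(z[:, None] - zpsi, 0, None)
           + coef["c_mat"][None, :] * np.asarray(mat_z)[:, None]
           + coef["c_moist"][None, :] * moist_z[:, None]
           + coef["c_bio"][None, :] * biomass_z[:, None]
           + coef["c_div"][None, :] * eta[:, None]
           + rng_fun.normal(0, noise["function"], (n, len(FUNCTION_NAMES))))
    for j, name in enumerate(FUNCTION_NAMES):
        env[name] = fun[:, j]

    truth = {
        "fault_elev": params.fault_elev,
        "pool_mixing": params.pool_mixing,
        "mat_intercept": params.mat_intercept,
        "mat_lapse": params.mat_lapse,
        "site_elevations": site_elev.tolist(),
        "geo_step": params.geo_step,
        "geo_step_sign": step_sign,
        "diversity_effect_weathering": params.diversity_effect_weathering,
        "diversity_effect_mat": params.diversity_effect_mat,
        "sensitive_fraction": params.sensitive_fraction,
        "otu_niche": {k: (v.astype(int).tolist() if v.dtype == bool else v.tolist())
                      for k, v in otus.items()},
        "plant_niche": {k: (v.astype(int).tolist() if v.dtype == bool else v.tolist())
                        for k, v in plants.items()},
        "function_names": list(FUNCTION_NAMES),
        "function_groups": dict(FUNCTION_GROUPS),
        "function_coefficients": {k: v.tolist() for k, v in coef.items()},
        "seed": params.seed,
    }

    return SyntheticBundle(
        sample_frame=env,
        plant_matrix=plant_matrix,
        otu_matrix=otu_matrix,
        plant_attributes=plant_attributes,
        taxonomy=taxonomy,
        truth=truth,
    )


def simulate_two_mountains(
    params: SimulationParams | None = None,
    offset_params: dict | None = None,
) -> tuple[SyntheticBundle, SyntheticBundle]:
    """Two transects sharing the fault elevation and species pools.

    ``offset_params`` overrides fields of the second mountain (commonly
    ``site_elevations`` or an ``elev_offset`` shifting every site); its noise
    and sampling use an independent seed derived from the base seed.  Raises
    if the two elevation ranges do not overlap.
    """
    params = params or SimulationParams()
    offset_params = dict(offset_params or {})
    elev_offset = float(offset_params.pop("elev_offset", 0.0))

    fields_b = asdict(params)
    fields_b.pop("site_elevations", None)
    fields_b.update(offset_params)
    params_b = SimulationParams(**fields_b)
    site_b = params.elevations() + elev_offset if "site_elevations" not in offset_params \
        else np.asarray(offset_params["site_elevations"], float)
    params_b.site_elevations = site_b.tolist()
    params_b.n_sites = len(site_b)

    if site_b.min() > params.elevations().max() or site_b.max() < params.elevations().min():
        raise ValueError("the two mountains' elevation ranges do not overlap")
    if params_b.fault_elev != params.fault_elev:
        raise ValueError("the two mountains must share the fault elevation")

    bundle_a = simulate_mountain(params, mountain="A")

    # Same taxa stream (shared pools/niches), independent noise streams: swap in
    # seed-derived sub-streams by re-running with the taxa stream pinned.
    bundle_b = _simulate_with_shared_taxa(params_b, params.seed, mountain="B")

    tol = float(offset_params.get("pairing_tol", 100.0))
    pairs = match_elevations(params.elevations(), site_b, tol)
    bundle_a.truth["matched_pairs"] = pairs
    bundle_b.truth["matched_pairs"] = pairs
    return bundle_a, bundle_b


def _simulate_with_shared_taxa(params_b: SimulationParams, taxa_seed: int,
                               mountain: str) -> SyntheticBundle:
    """Simulate mountain B reusing mountain A's taxa stream for the truth block."""
    # taxa stream must match the base seed's first spawn; noise streams differ.
    base_streams = np.random.SeedSequence(taxa_seed).spawn(6)
    noise_streams = np.random.SeedSequence([taxa_seed, 1_000_003]).spawn(6)
    merged = [base_streams[0]] + list(noise_streams[1:])
    return simulate_mountain(params_b, mountain=mountain, _seed_sequences=merged)


def match_elevations(elev_a: np.ndarray, elev_b: np.ndarray,
                     tol: float = 100.0) -> list[dict]:
    """Greedy nearest-elevation site pairing within ``tol`` metres."""
    pairs = []
    for j, eb in enumerate(np.asarray(elev_b, float)):
        i = int(np.argmin(np.abs(np.asarray(elev_a, float) - eb)))
        if abs(elev_a[i] - eb) <= tol:
            pairs.append({"site_a": i, "site_b": j,
                          "elev_a": float(elev_a[i]), "elev_b": float(eb)})
    return pairs
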