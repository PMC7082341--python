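# elevbreak

Breakpoint analysis of biodiversity and ecosystem functions along mountain
elevational gradients, with driver attribution to contemporary versus
geological predictors.

Mountain transects that cross tectonic faults often show abrupt shifts in
plant and soil-bacterial communities and in ecosystem functioning at a
particular elevation, rather than smooth turnover. `elevbreak` is a Python
library for ecologists and biogeochemists who want to (i) locate such
elevational breakpoints in plot-level survey data, (ii) summarize many
ecosystem function measurements into multifunctionality indices, and
(iii) ask how much of the pattern is explained by contemporary environments
(climate, soil pH, moisture, biota) versus long-term geology (parent-rock
mineralogy, chemical weathering). A seeded synthetic-mountain generator with
a planted fault provides ground truth for every stage, so the whole pipeline
is testable end to end.

## Methods at a glance

* **Piecewise breakpoint regression** — the continuous two-segment model
  *y* = β₀ + β₁·*x* + β₂·(*x* − ψ)₊, with the breakpoint ψ found by SSE grid
  search (1 m grid) inside a candidate band (default 1800–3000 m), a
  bootstrap percentile CI for ψ, and an approximate F-test of the
  improvement over a single line (null calibration verified by simulation).
* **Compositional turnover** — Bray–Curtis dissimilarity
  Σ|x−y| / Σ(x+y) between adjacent sites with a one-way PERMANOVA pseudo-F
  (exhaustive label enumeration when feasible, seeded permutations with the
  add-one rule otherwise); the breakpoint pair maximizes the within-band
  rank sum of pseudo-F and dissimilarity.
* **Split density** — a gradient-forest-style profile: one variance-reduction
  regression tree per taxon on elevation, split thresholds pooled into an
  importance-weighted kernel density and standardized by the sampling
  density of elevations.
* **Ordination** — correspondence analysis with detrending by segments (DCA,
  default 26 segments) for communities and function composition; PCA for
  mineral and metal panels.
* **Multifunctionality (EMF)** — per-sample mean of Z-scored functions, for
  all 38 functions and per functional group, plus a subset-permutation curve
  (k = 10…38) testing robustness to the number of functions. Multidiversity
  (MD) averages standardized richness of plants, whole bacteria and dominant
  phyla.
* **Driver attribution** — predictor dereplication at |r| > 0.7, AICc
  all-subsets model averaging with Akaike weights (conditional averaging),
  stepwise regressions quantifying the explained-variance increment from the
  geological block (significance by nested-model ANOVA), variation
  partitioning on adjusted R², and recursive least-squares path analysis
  over composite variables with direct/indirect effect decomposition and
  SRMR. Weathering is summarized by the chemical index of alteration,
  CIA = 100·Al₂O₃/(Al₂O₃+CaO*+Na₂O+K₂O), and Ti/Fe, Ti/Al, Mg/Al, Ca/Al.

## Worked example

```python
import numpy as np
from elevbreak import (SimulationParams, simulate_mountain,
                       piecewise_fit, adjacent_turnover, split_density)

bundle = simulate_mountain(SimulationParams(seed=1))     # fault planted at 2400 m
x = bundle.sample_frame["elevation"].to_numpy()

c2 = np.array(bundle.truth["function_coefficients"]["c2"])
planted = bundle.truth["function_names"][int(np.argmax(np.abs(c2)))]
fit = piecewise_fit(x, bundle.sample_frame[planted].to_numpy(), n_boot=199, seed=0)

site_elev = bundle.sample_frame.groupby("site_id")["elevation"].mean()
prof = adjacent_turnover(bundle.otu_matrix, bundle.sample_frame["site_id"],
                         site_elev, n_perm=199, seed=0)
dens = split_density(bundle.otu_matrix, x)
```

Running `python examples/01_simulate_and_breakpoints.py` (the script version
of the above) prints:

```
planted fault: 2400 m; site spacing 180 m
piecewise fit of 'wson': breakpoint 2426 m (95% CI 2367-2489), p=2.41e-76
turnover scan: strongest adjacent-site shift at 2410 m (pseudo-F=437.1, dissimilarity=0.87)
split-density peak: 2419 m (1784 tree splits pooled)
```

All three independent localizations land within one site spacing (180 m) of
the planted fault: the regression sees the kink in a function response, the
turnover scan sees the species-pool replacement in the OTU table, and the
split density sees it accumulated over the single-taxon trees. The other
scripts in `examples/` walk through multifunctionality (`02`), driver
attribution (`03`) and the two-mountain comparison (`04`); the full pipeline
is also available as a CLI (`elevbreak simulate`, `elevbreak run`, ...).

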