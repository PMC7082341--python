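"""Contemporary vs. geological drivers of multidiversity.

Builds the multidiversity index (plants + bacteria + dominant phyla) from a
simulated transect, then attributes its variance: AICc model averaging over
dereplicated predictors, the explained-variance increment from adding the
geological block, variation partitioning, and a composite-variable path model
with direct/indirect effect decomposition.
"""

import pandas as pd

from elevbreak import (SimulationParams, simulate_mountain, multidiversity,
                       geochem_indices, pca, dca, dereplicate_predictors,
                       all_subsets_average, geo_increment, variation_partition,
                       composite_score, path_fit)
from elevbreak.simulate import _MINERALS

bundle = simulate_mountain(SimulationParams(seed=1))
sf = bundle.sample_frame

rich = pd.DataFrame({"bacteria": (bundle.otu_matrix > 0).sum(axis=1),
                     "plants": (bundle.plant_matrix > 0).sum(axis=1)})
md = multidiversity(rich).md

geochem = geochem_indices(sf)
minerals = pca(sf[list(_MINERALS)]).scores[["PC1", "PC2"]]
plant_comp = dca(bundle.plant_matrix).scores["DCA1"]

contemporary = sf[["mat", "map", "ph", "moisture"]].assign(plant_dca1=plant_comp)
geological = pd.concat([geochem[["cia", "ca_al", "mg_al", "ti_fe"]],
                        minerals.rename(columns={"PC1": "min_pc1", "PC2": "min_pc2"})],
                       axis=1)

contemp_d, log_c = dereplicate_predictors(contemporary, md)
geo_d, _ = dereplicate_predictors(geological, md)
print(f"dereplication kept {list(contemp_d)} + {list(geo_d)}; dropped: {log_c or 'none'}")

avg = all_subsets_average(md, pd.concat([contemp_d, geo_d], axis=1))
print("\nmodel-averaged standardized effects on multidiversity (|beta|, importance):")
for name in avg.beta.abs().sort_values(ascending=False).index[:5]:
    print(f"  {name:10s} beta={avg.beta[name]:+.2f}  importance={avg.importance[name]:.2f}")

inc = geo_increment(md, contemp_d, geo_d)
print(f"\ngeological increment: R2 {inc.r2_contemporary:.3f} -> {inc.r2_with_geology:.3f} "
      f"(+{inc.percent_increase:.1f}%), ANOVA p={inc.p_value:.3g}")

vp = variation_partition(md, contemp_d, geo_d)
print(f"variation partitioning: contemporary-unique {vp.a:.3f}, "
      f"geology-unique {vp.b:.3f}, shared {vp.c:.3f}, residual {vp.d:.3f}")

# composite-variable path model
data = pd.DataFrame(index=sf.index)
for name, table in (("climate", sf[["mat", "map"]]), ("local", sf[["ph", "moisture"]]),
                    ("weathering", geochem[["cia", "ca_al", "mg_al", "ti_fe"]]),
                    ("parent_rock", minerals)):
    data[name], _ = composite_score(table, md)
data["biotic"] = plant_comp
data["MD"] = md
edges = [("parent_rock", "weathering"), ("climate", "local"), ("weathering", "local"),
         ("climate", "biotic"), ("weathering", "biotic"), ("local", "biotic"),
         ("climate", "MD"), ("weathering", "MD"), ("local", "MD"), ("biotic", "MD")]
pm = path_fit(data, edges, outcome="MD")
print(f"\npath model (SRMR={pm.srmr:.3f}, R2[MD]={pm.r2['MD']:.2f}):")
for v in ("climate", "weathering", "parent_rock", "local", "biotic"):
    print(f"  {v:12s} direct={pm.direct[v]:+.2f}  indirect={pm.indirect[v]:+.2f}  "
          f"total={pm.total[v]:+.2f}")
print("-> weathering carries the planted direct geological effect on diversity;")
print("   parent rock acts only indirectly, through weathering.")
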