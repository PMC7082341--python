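"""Cross-mountain consistency of the elevational breakpoint.

Simulates two transects that share the fault elevation and species pools but
differ in site elevations (offset half a spacing) and sampling noise, then
compares their site-level bacterial communities at matched elevations.  The
matched-pair similarity minimum marks the shared fault.
"""

from elevbreak import SimulationParams, simulate_two_mountains, cross_mountain

a, b = simulate_two_mountains(SimulationParams(seed=4, pool_mixing=1.0),
                              {"elev_offset": 90.0})

site_a = a.otu_matrix.groupby(a.sample_frame["site_id"]).mean()
site_b = b.otu_matrix.groupby(b.sample_frame["site_id"]).mean()
elev_a = a.sample_frame.groupby("site_id")["elevation"].mean().loc[site_a.index]
elev_b = b.sample_frame.groupby("site_id")["elevation"].mean().loc[site_b.index]

res = cross_mountain(site_a, site_b, elev_a.to_numpy(), elev_b.to_numpy(),
                     pairing_tol=100.0, breakpoint=a.truth["fault_elev"],
                     n_perm=199, seed=0)

print(f"{len(res.matched)} matched site pairs (tolerance 100 m)")
print("matched-elevation similarity profile (1 - Bray-Curtis):")
for row in res.matched.itertuples():
    marker = "  <-- minimum" if row.elev == res.min_similarity_elev else ""
    print(f"  {row.elev:6.0f} m   {row.similarity:.3f}{marker}")
print(f"\nshared fault planted at {a.truth['fault_elev']:.0f} m; similarity minimum "
      f"at {res.min_similarity_elev:.0f} m — the pair straddling the fault compares")
print("below-fault with above-fault species pools, hence the dip.")

below = res.slopes[res.slopes["side"] == "below"]
n_sig = int((below["p_value"] < 0.05).sum())
print(f"\nsimilarity-vs-elevation slopes (mountain B sites vs below-fault A sites): "
      f"{n_sig}/{len(below)} significant at alpha=0.05 (permutation test)")
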