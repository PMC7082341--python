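# Methods

This note documents the models implemented in `elevbreak`, the choices made
where the methodology was genuinely open, and what the synthetic-data
generator does and does not emulate.

## The synthetic mountain

`simulate_mountain` emulates a plot-level survey of a montane elevational
gradient crossing a tectonic fault. Defaults describe the study design the
package is built around: 18 sites evenly spaced over 700–3760 m (inter-site
spacing ≈ 180 m), 10 plots per site (180 samples), a fault at ψ* = 2400 m
inside the 1800–3000 m candidate band, 300 bacterial OTUs and 40 plant taxa,
and 16S-like sequencing at 10 000 reads per sample (matching the default
rarefaction depth downstream).

**Communities.** Each taxon has a Gaussian (coenocline) niche
f(e) = A·exp(−(e−μ)²/2σ²) with optimum μ, tolerance σ (lognormal around
350 m) and peak abundance A. Taxa belong to a below-fault or above-fault
species pool; on the wrong side of the fault expected abundance is
multiplied by (1−κ), with the abruptness κ = 0.9 by default (κ = 1 is hard
replacement, κ = 0 removes the fault from the communities entirely). OTU
counts are multinomial draws of the renormalized expected relative
abundances at the stated depth, so every row sums exactly to the sequencing
depth — the simplest count model satisfying the rarefaction precondition
(a Dirichlet-multinomial overdispersion layer was considered and left out).
Plant counts are Poisson draws of the same niche model at plant scale.

**Environment and geology.** Mean annual temperature follows a linear lapse
MAT = a − b·e (a = 24 °C, b = 0.0055 °C/m) with plot-level noise;
precipitation, pH and moisture are linear trends with noise. Mineral
(quartz, plagioclase, K-feldspar, amphibole, muscovite, chlorite), metal
(Ca, Fe, Mg, Al, K, Na, Mn, Ti) and molar oxide columns take a step of
random sign at the fault (size `geo_step`, in units of the column's
within-gradient scale) plus noise; Al₂O₃ steps upward so the chemical index
of alteration rises across the fault.

**Planted driver structure.** A per-plot habitat-suitability signal
η = θ_w·z(CIA) + θ_m·z(MAT) (defaults θ_w = 1.5, θ_m = 0.5) governs the
occupancy of a random half of the taxa ("sensitive" taxa), each present in
a plot with probability logistic(0.5 + η). This makes richness — and hence
multidiversity — respond *directly* to realized weathering and temperature,
while ecosystem functions receive η only as one of their inputs, so geology
reaches functions *indirectly* through diversity. The effect sizes are set
so that the planted structure is recoverable by the downstream analyses on
a single transect (the package's design goal is ground-truth validation,
and an undetectable plant would validate nothing); with these defaults the
weathering composite carries the largest direct path effect on
multidiversity in roughly nine of ten simulated transects.

**Ecosystem functions.** The 38 function columns (five groups: plant
biomass 14, microbial biomass 8, enzyme activities 5, photosynthetic
bacteria 4, soil nutrients 7) are generated as
y = c₀ + c₁·z + c₂·(z−z_ψ)₊ + c_mat·z(MAT) + c_moist·z(moisture)
  + c_bio·z(plant biomass) + c_div·η + ε, with elevation z in km and noise
SD 0.5. A random 60% of functions carry a planted slope change c₂
(|c₂| ∈ [4, 6] per km); the remainder are purely smooth. The slope-change
magnitude dominates the smooth covariate terms (|c_bio| ~ 0.2,
|c_div| ~ 0.15) because a hinge fit of a kink co-located with step- and
hump-shaped confounders is biased when those terms are comparable in size;
the confounders are kept non-zero so the driver analyses still have real
mediated structure to find. All coefficients are stored in `truth` and
round-trip losslessly through `truth.json`.

**What the generator does not emulate:** spatial autocorrelation within and
between sites, read-level sequencing error and chimeras, compositional
(closure) artifacts beyond the multinomial itself, phylogenetic structure
among taxa, and climate interpolation error. Passing the recovery tests
therefore demonstrates the statistical machinery is correct on data obeying
the stated model, not that field data meet that model.

**Seeding.** One seed per bundle; per-table generators are spawned
deterministically from it (`SeedSequence.spawn`), so equal parameters and
seed give bit-identical bundles. The second mountain of
`simulate_two_mountains` reuses the first mountain's taxon stream (shared
pools and niches) and draws noise from an independently derived stream.

## Breakpoint machinery

**Piecewise regression.** The continuous broken-stick model
y = β₀ + β₁x + β₂(x−ψ)₊ is fit by ordinary least squares at every candidate
ψ on a grid (default step 1 m) inside the band, keeping the SSE minimizer;
the candidate set requires at least two distinct elevations on each side.
The grid solve is vectorized through 3×3 normal equations on centred data
and the winner is refit by `lstsq` for the reported coefficients, so the
result is identical to a naive per-candidate loop. The significance of the
breakpoint (`p_improvement`) is an F-test of the piecewise against the
single-line model charging two extra parameters (β₂ and ψ). Because ψ is
searched, the test is approximate (the non-regular-parameter problem); its
null behaviour is therefore checked by Monte-Carlo in the test suite, where
it rejects at ≈3–4% at nominal α = 5% for the default design — slightly
conservative, which is acceptable for a screening census. Bootstrap CIs are
case-resampling percentile intervals (999 replicates by default); when more
than 20% of replicate estimates sit within one grid step of a band edge the
interval is flagged `edge_limited`.

**Turnover selection.** For each adjacent site pair: mean between-site
Bray–Curtis dissimilarity and a two-group PERMANOVA. The selected breakpoint
is the pair inside the band maximizing the rank sum of pseudo-F and
dissimilarity, with ties broken by pseudo-F — a joint rule is needed because
"highest pseudo-F and dissimilarity" can disagree; rank summation treats
the two statistics symmetrically without unit problems. The reported
breakpoint elevation is the midpoint of the pair.

**PERMANOVA.** SS_total = (1/n)Σ_{i<j}d²_ij, within-group sums analogous;
pseudo-F = (SS_between/(g−1))/(SS_within/(n−g)). When the number of distinct
label assignments is ≤ the requested permutation count, the null is
enumerated exhaustively and p is the exact proportion of assignments with
F ≥ F_obs (ties counted, conservative); otherwise seeded random permutations
with the add-one rule. One-way designs only.

**Split density.** One `DecisionTreeRegressor` (depth 3, minimum leaf 5)
per taxon on elevation alone; each internal node contributes its threshold
weighted by its impurity decrease, normalized per taxon so abundant taxa do
not dominate. Thresholds are pooled by Gaussian kernel density (Silverman
bandwidth; a fixed 50 m kernel for degenerate single-location split sets)
and divided by the kernel density of the observed elevations. This is a
deliberate simplification of the gradient-forest ensemble to one tree per
taxon: with a single predictor there is no variable-selection randomness
for a forest to average over, and the split locations are what matters.

**DCA.** Correspondence analysis via SVD of the standardized residual
matrix; axis 2 is detrended against axis 1 by dividing the axis-1 range
into 26 equal segments (default) and centring axis-2 scores within each.
Hill's nonlinear rescaling is intentionally not implemented, so scores are
in raw CA units, not SD units; gradient ordering and arch suppression — the
two properties the analyses rely on — are unaffected, and the segment count
is configurable for sensitivity checks.

## Multifunctionality

Z-scores use the sample SD (n−1). EMF is the row mean of Z-scores over the
chosen function set; group EMFs use the five-group map, and group EMFs
weighted by group size average exactly to the overall EMF. Missing entries
are excluded pairwise with a 50% minimum row coverage. The subset curve
draws 1000 (configurable) uniform k-subsets per k — exhaustively when
C(K,k) is smaller — and records the Pearson correlation of each subset EMF
with the full EMF; by linearity of the mean, subset-EMF is unbiased for the
full EMF at every k, which the tests verify exhaustively at K = 6.
Multidiversity uses Z-score standardization by default (max-scaling is
available), and "dominant phyla" means prevalence ≥ 80% after phylum
aggregation, boundary inclusive, with Proteobacteria reported at class rank.

## Driver attribution

Dereplication drops one member of every predictor pair with Pearson
|r| strictly above 0.7 (a 1e−10 tolerance keeps |r| = 0.7 exactly on the
"keep both" side), resolving conflicts from the strongest correlation down
and keeping the member better correlated with the response (keep-first is
available). Model averaging fits all predictor subsets (≤ 15 predictors) on
Z-scored data, weights models by AICc (k counts the intercept and residual
variance), and averages each coefficient over the models containing it
(conditional averaging); relative importance is the summed weight of those
models. Stepwise selection is forward+backward by AIC from the null model.

The geological increment locks the stepwise-selected contemporary terms and
lets the geological block enter stepwise on top; the percent R² increase is
reported from those selected models. Its *significance*, however, is an
ANOVA between the models excluding and including the **full** geological
block: testing only stepwise-selected geological terms would inherit the
selection bias and over-reject badly under the null, whereas the full-block
F-test has fixed degrees of freedom and is exactly calibrated (verified at
≈5% over 200 null simulations). The subset census augments every
contemporary-only subset with the full block for the same reason.

Variation partitioning uses adjusted R²: a = adjR²(AB) − adjR²(B),
b = adjR²(AB) − adjR²(A), c = adjR²(A) + adjR²(B) − adjR²(AB),
d = 1 − adjR²(AB); the shared fraction c may be negative (suppression).

The path model is recursive least squares: every endogenous node regressed
on its parents after Z-scoring. This intentionally replaces full
maximum-likelihood SEM — coefficients of a fully recursive standardized
system are identical, and per-equation fitting is transparent and fast —
but it does not produce χ²/CFI global fit statistics; model fit is judged by
SRMR (RMS difference between observed and model-implied correlations, with
the implied matrix built as (I−B)⁻¹Ψ(I−B)⁻ᵀ keeping the observed exogenous
covariances) and alternative structures compared by summed per-equation
AIC. Direct, indirect (sum of path products excluding the direct edge) and
total effects satisfy total = direct + indirect by construction, and the
total effect of a source equals its simple standardized slope in saturated
recursive models. Composites are regression-weighted sums of Z-scored
indicators, re-standardized. CIA takes its inputs as molar oxide
proportions with CaO* already silicate-corrected — the correction requires
apatite/carbonate data the pipeline does not model.

α = 0.05 throughout, with no multiple-testing correction applied to the
per-facet breakpoint census.

## Pipeline defaults and problem sizes

`RunConfig` defaults: band 1800–3000 m, rarefaction depth 10 000,
199 permutations and 199 bootstrap replicates per pipeline stage (the
standalone functions default to 999; the pipeline fits ~50 responses, and
199 keeps the seeded percentile machinery identical while bounding the
per-run cost), subset curve with 200 draws per k. All stage seeds derive
deterministically from `RunConfig.seed`; `summary.json` excludes file paths
and timestamps, so one config and seed give byte-identical summaries. The
validation suite uses 100 simulated transects for recovery rates and 200
null simulations per calibration check; spot checks are exact.

## Known limitations

Breakpoint significance is approximate (see above) and single-breakpoint
only — no multi-segment models. DCA omits nonlinear rescaling, so axis
lengths are not in beta-diversity SD units. The path analysis has no latent
measurement model; composites are formative, not reflective. PERMANOVA has
no dispersion-heterogeneity companion test. The dereplication keep-rule is
greedy, not globally optimal. Faith's phylogenetic diversity and
UniFrac-type metrics are out of scope (no tree input).
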