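# Methods

This note documents the models, parameter choices and limitations of
`latentplan`, in the order the pipeline runs them.

## Ordinal threat status

The response is an ordinal score on a 10-point scale built from an
IUCN-style category and a population trend: base scores LC = 1, NT = 3,
VU = 5, EN = 7, CR = 9, plus one point when the trend is decreasing.
This mapping is a documented stand-in for whatever coding a given study
uses; it is monotone in category severity, worsened by decline, and
reaches every level from 1 to 10. The same mapping drives both the
synthetic status generator and the target-selection rule (EN-or-worse
means an encoded status ≥ 7), so the package is internally consistent.
The ordinal response is treated as numeric in the regression — the
familiar pseudo-numeric compromise of comparative extinction-risk
analysis — rather than through a cumulative-link model; that choice
keeps latent risk interpretable as a difference of fitted and observed
scores on one scale.

## The GLS risk model

`PhyloSpatialGLS` fits `y = Xβ + ε` with `ε ~ N(0, σ²V)` and

```
V = w_p V_phylo + w_s V_space + (1 − w_p − w_s) I
```

- `V_phylo`: for an ultrametric tree of depth `T`, the correlation
  between two species is the depth of their most recent common
  ancestor over `T`, i.e. `1 − d_ij/(2T)` with `d` the patristic
  distance. Unit diagonal by construction.
- `V_space`: `exp(−d_ij/ρ)` on Euclidean distances between range
  centroids; `ρ` (km) sets the decay scale.
- The blend is a convex combination, the simplest identifiable way to
  honour simultaneous phylogenetic and spatial non-independence. How
  the two structures should enter is genuinely open; an alternative
  would be a product or a nested structure. Weights and `ρ` can be
  estimated by profile maximum likelihood over a coarse simplex × grid
  (`profile_covariance`), or fixed from configuration — the default,
  since the profile surface is flat at small n.

Estimation whitens through the Cholesky factor of `V`. The residual
variance in the likelihood is the ML estimator `RSS_V/n` (so AICc
comparisons across fixed-effects structures are valid), while standard
errors use the df-corrected `RSS_V/(n−k)` with t reference on `n−k`
degrees of freedom — with `V = I` the output reproduces textbook OLS
inference exactly (cross-checked against statsmodels in the tests).
The AICc parameter count includes the residual variance. Positive
definiteness of `V` is enforced with an escalating diagonal jitter
(warned, starting at 1e-10) in the rare semidefinite case.

## Predictor preparation

Spatial predictors are zonal means over each species' range cells;
range size is the occupied-cell count times cell area; invader overlap
is the proportion of range cells with the invader present; centroids
are means of occupied cell centres. Columns with |skewness| > 1 (and
no negative values) are log-transformed — `log(x + ε)` with
`ε = half the smallest positive value` where zeros occur — then all
columns are z-scored. The quadratic body-mass term is the standardized
square of the standardized log mass (a centred quadratic), appended
after the transform. The VIF screen removes the worst collinear
predictor while any VIF = 1/(1−R²) exceeds 5 (threshold configurable;
the literature offers no single value). Perfectly collinear columns are
removed with a warning rather than an error, since a duplicated layer
should not kill a pipeline run.

## Stepwise minimum adequate model

Backward phase: propose deleting the predictor with the highest p-value
(ties by smaller |t|, then column order); accept iff AICc improves by
at least 2; stop at the first rejected proposal. Forward phase: try
re-adding each deleted predictor in deletion order under the same rule.
The quadratic term is deleted before its linear partner and never
re-enters without it. Two consequences worth knowing: with large n the
AICc penalty drop for one parameter approaches 2, so pure-noise
predictors are often *retained* (the rule is conservative about
deletion); and the search is a heuristic — it explores one path, not
the lattice of subsets. The full decision trace (every proposal, both
AICc values, accepted or not) is returned and serialized.

## Latent risk

The chosen model is refit once per phylogeny in the sample (covariance
rebuilt per tree, coefficients re-estimated), and latent risk is the
across-tree mean fitted status minus the observed status, with its
positive part carried separately. Averaging over trees absorbs
phylogenetic uncertainty; the per-species SD of fitted values is
reported. Risk maps: total maps sum values over species present in a
cell; mean maps average them; the positive-latent mean uses only
species with `L > 0`. Cells with no qualifying species are no-data
(NaN), not zero — an empty mean is undefined, and zeros would read as
"present but riskless" on a map.

## Planning units, tenure and cost

Flat-top hexagons (side default 4 km at demo scale; the closed forms
`perimeter = 6s`, `area = (3√3/2)s²` are exposed directly) are clipped
to the region boundary; the clipped fraction `w ∈ (0,1]` multiplies
both the proxy cost and the feature amounts, and PUs with `w < 0.01`
are dropped. Tenure is the majority class by covered cells, with exact
ties resolved by a fixed conservation-status-first priority (PA > IPA >
Indigenous freehold > Native Title pastoral use > Native Title > ILUA
pastoral use > ILUA > pastoral > other). Where the majority class is
Native Title or ILUA and a pastoral-lease overlay covers the majority
of the PU, the combined pastoral-use class applies. Costs take the
*modal* MEI and HII over covered cells (ties at the mode resolve to the
smaller value; the synthetic generator quantizes both layers so modes
are well defined), min–max normalize each across PUs, rescale to
[0.01, 100] (the floor avoids near-free PUs dominating solutions), and
blend 0.4/0.6 before the `w` weighting. Normalizing before blending
keeps the blended cost inside [0.01, 100]; the alternative order would
not.

Feature amounts `a_ij` assign every grid cell to the PU containing its
centre (shared-edge ties to the lowest PU id, so the assignment is a
deterministic partition) and multiply by cell area and `w`. The species
total used in coverage denominators is the in-region weighted amount
`Σ_i a_ij`, so a solution selecting every PU scores exactly 100%.

## Targets

Target species are the high-risk tail: encoded status ≥ 7 (EN/CR) for
the current criterion, mean latent risk > 1.5 for the latent criterion
(both thresholds configurable; a top-decile mode exists as well —
category and threshold rules are the default because that is how such
target sets are defined in practice). Raw risk is min–max rescaled to
[0.25, 0.75] *within each criterion's target set* (scaling jointly
across criteria would let one criterion's outliers compress the
other's spread); if all raw values tie, everything maps to the
midpoint 0.5. Then `P = min(0.4R + 0.6A, 0.75)` and `T = P ×` the
species' in-region amount. `P` is bounded in [0.1, 0.75] and monotone
in both arguments.

## Prioritization

The minimum-set ILP is solved by HiGHS via `scipy.optimize.milp` at a
relative gap of 0 (proven optimality). Locked-in PUs (the PA/IPA
estate) are fixed to 1 and contribute their feature amounts toward
targets (a configurable convention); locked-out PUs are fixed to 0.
Objective 2 locks out everything that is not Native Title (with or
without pastoral use) or Indigenous freehold. Feasibility is checked
before solving; failure raises a structured error listing each
species' shortfall in km². Ties among equal-cost optima are pinned by
a second solve that holds the optimal cost and minimizes the sum of
selected PU indices — a deterministic, id-ordered tie-break (a cost
perturbation small enough not to bias the optimum would sit below the
solver's tolerances). Reported metrics: proxy cost and tenure
proportions over newly selected PUs (the locked-in estate is sunk);
area, boundary length (exposed edges of the union of selected
polygons; region-border edges count fully) and per-species coverage
over the whole selected network; mean coverage is the unweighted mean
over all species, not only targets. A greedy
shortfall-reduction-per-cost heuristic is included as a baseline and
for instances beyond exact reach; it never beats the exact solver.

## Scenarios

The 2 × 2 grid (criterion × objective) shares one PU table and feature
matrix. Selection frequency counts *newly selected* PUs only — the
locked-in estate would trivially score 4 everywhere and swamp the
signal (a switch includes it). Note a structural ceiling: PUs on
tenure ineligible under objective 2 can never exceed frequency 2, so
the high-priority set (frequency 4) is by construction drawn from
Indigenous-held and reserved land. The report bundle (metrics CSV,
frequency GeoJSON, tenure × frequency and per-scenario proportion
tables, target tables, manifest with config hash and seed) is
deterministic: identical config and seed give byte-identical output.

## The synthetic study system

The generator emulates a tropical-savanna study region at desk scale
(default demo: 60 × 60 cells of 1 km; the generator's native default is
100 × 100, echoing a 1-km analysis grid):

- **Phylogenies**: pure-birth trees grown to the species count, one
  shared taxon namespace, so the sample mimics a posterior set over a
  fixed species list. Ultrametric by construction.
- **Traits**: log-scale Brownian motion along the tree plus independent
  tip noise; root values and rates chosen to give mammal-like body
  masses (~150 g median), ages at first reproduction (~1 yr), litters
  per year and litter sizes.
- **Landscape**: Gaussian-filtered white noise (filter scale 6 cells)
  mapped through the normal CDF onto realistic ranges — temperature of
  the wettest quarter 24–34 °C, fire frequencies, HII as integers 0–61,
  MEI rounded to $100 (quantized so modal zonal statistics are
  meaningful) — and thresholded smooth fields for fox and cane-toad
  presence.
- **Ranges**: spreading-dye growth (uniformly random frontier accretion,
  4-connectivity) to an exact target size; sizes log-normal between 5%
  and 40% of the region. The floor mirrors the comparative-model
  species pool, which excludes range-restricted species.
- **Tenure**: classes grown as quota-limited contiguous patches (≤ 1%
  of the landscape each), realized proportions exact to one cell. The
  default mix is Indigenous-dominant (PA+IPA 12%; of the rest, 42%
  Indigenous freehold, 32% Native Title, 4% ILUA, 14% pastoral, 8%
  other), emulating a region where Indigenous-held land dominates —
  which is also what keeps the voluntary-declaration objective
  feasible, the same feasibility consideration that motivates the 75%
  target cap. A pastoral-lease overlay covering ~40% of Native
  Title/ILUA land makes the combined pastoral-use classes occur.
- **Statuses**: latent risk `Xβ_true` plus correlated noise (default
  weights 0.4/0.2/0.4, σ² = 2, ρ = 20 km), cut at its empirical deciles
  into the 10-point scale — equal-probability bins, so every level is
  populated in expectation. A suppressed 10% of species have 3 points
  subtracted (floored at 1); these are the species latent risk should
  recover. `σ² = 0` is allowed as the degenerate noise-free limit.
- **In-region proportion A**: drawn U(0.15, 0.7) per species, standing
  in for distributions that extend beyond the study region (simulating
  the outside world explicitly would buy nothing at desk scale).

What the generator does *not* emulate: real geography and cadastral
shapes, observation error in occurrence data, non-stationary spatial
covariance, correlated predictors with causal structure, and
range-restricted endemics. Passing tests therefore demonstrate that the
estimators and the optimization behave correctly under the stated
generative model — not that any particular real landscape satisfies
those assumptions. Feasibility of the voluntary-declaration objective
depends on the landscape: configurations where a target species' range
sits mostly on ineligible tenure raise an explicit shortfall error
rather than silently relaxing targets.

## Numerical choices and problem sizes

Whitening uses Cholesky factors throughout; a design condition number
above 1e12 raises a rank-deficiency error naming the suspect columns.
Determinism: every random stage derives its seed from the single config
seed by fixed offsets. The test-suite problem sizes (n = 128 species
for recovery tests, 200 GLS replicates, 100 latent-risk replicates with
5 trees, exact-vs-enumeration instances up to 15 PUs, demo landscape
60 × 60 with ~120 PUs) were chosen so the whole suite completes in well
under a minute while keeping Monte-Carlo standard errors small relative
to the tested effects.

## Known limitations

- The ordinal response is modelled as Gaussian; at the scale ends the
  latent-risk difference is attenuated (a species at status 10 cannot
  be under-listed).
- The stepwise search is path-dependent; equally good subsets can be
  missed, and with large n the ΔAICc ≥ 2 deletion rule retains noise.
- The covariance blend is estimated on a coarse grid when profiling;
  weight uncertainty is not propagated into latent risk.
- Boundary length uses the polygon union, so two PUs touching only at
  a corner are treated as disjoint (correct, but worth knowing).
- The exact solver is intended for up to a few thousand PUs; beyond
  that, set a positive gap or use the greedy baseline.
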