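# Methods

## The study template

The pipeline analyses a paired-tile intertidal experiment: at each of
`n_transects x stations_per_transect` stations, two settlement tiles —
one flat, one pitted ("heterogeneous") — share a position along an
emersion-stress gradient (emersion ratio = fraction of the year a tile is
tidally exposed).  Tiles are surveyed at `n_censuses` seasonal visits;
percent cover per taxon is estimated by point-count subsampling of images
(`n_points` grid points, default 500).  Stations are cut into low/mid/high
shore zones as emersion terciles with equal station counts (±1).  The
defaults (5 transects × 7 stations × 2 tiles, 11 censuses ≈ 3 years,
20 taxa in five functional groups) reproduce the scale of the field
system the package targets.

## Synthetic community generator

Each taxon *i* on tile *j* carries a latent Gaussian state

    eta_ijt = suit_ij + damp_j * (season_i(t) + u_ijt)

- `suit_ij`: a within-group "offset ladder" (step `taxon_offset_step`,
  default 0.35) plus a logistic emersion response per functional group
  plus station-level suitability noise (`suitability_sd`, default 0.7)
  shared by the two paired tiles.  A taxon with `suit_ij` below the
  presence threshold records zero cover on that tile, so richness is
  emergent rather than simulated directly.
- `season_i(t)`: one sinusoid per year with group-specific phase and
  amplitude; ephemeral algae peak opposite to barnacle recruitment, which
  creates genuine asynchrony for the metrics to detect.
- `u_ijt`: AR(1) noise (`ar1_rho` = 0.45, innovation SD `noise_sd` ×
  a group volatility scale), initialised at its stationary distribution
  so early censuses are not systematically calmer.

Expected cover is `cmax_g * sigmoid(eta)`; observed cover is a binomial
point count, `Binomial(n_points, E/100) / n_points * 100`, which bounds
covers in [0, 100] without truncation artifacts and gives the exact
closed-form sampling SD used in the tests.

Ground-truth causal pathways are named, signed dials:

| dial | default | mechanism |
|---|---|---|
| `heterogeneity->richness` | low 0.8 / mid 0.4 / high 0.0 | lifts the suitability of refuge-colonising groups (native barnacles, ephemerals, "other"), pushing marginal taxa over the presence threshold; zone-varying by design |
| `heterogeneity->pop_stability` | 0.35 | refugia: damps the whole temporal deviation (seasonal + stochastic) on pitted tiles |
| `heterogeneity->dominant` | −1.1 | pits reduce the dominant barnacle's cover (not its presence) |
| `heterogeneity->consumers` | −0.9 | pits restrict grazer movement and cover |
| `consumers->ephemeral` | −0.8 | grazing reduces ephemeral-algal mean cover *and* volatility |
| `dominant->pop_stability` | 0.65 | crowding: a space-monopolising dominant damps everything else's fluctuations |

Three modelling choices matter and were made deliberately: (i) refugia and
crowding damp the **total** temporal deviation, because the seasonal
component dominates per-taxon variability and a dial that damps only the
stochastic part would be statistically invisible; (ii) the suppression
dials act on cover magnitude but not presence, so they do not leak into
richness and the dials stay independent; (iii) presence and station
suitability are shared within a tile pair, so under a null scenario paired
tiles differ only by sampling noise.  Dial magnitudes were fixed once, at
values that give the pathways roughly the power a single 70-tile study
would need to detect them, with the positive (refugia, richness →
asynchrony) and negative (dominant, consumer suppression) chain products
approximately cancelling — the counteracting-pathways scenario is the
package default.

What the generator does **not** emulate: calendar-irregular censuses
(metrics use census index only), within-tile spatial structure (pits act
only through their statistical consequences), canopy/understorey
distinction beyond summed strata (totals may exceed 100%), recruitment
pulses, or taxon covariances beyond seasonality and the named dials.
Passing tests therefore show the *machinery* is correct and calibrated,
not that any particular field system satisfies the default causal model.

## Stability decomposition

All five metrics are computed per tile from the census × taxon cover
matrix after ordinary-least-squares detrending on census index, applied
per taxon; because OLS detrending is additive, the total's residuals
equal the summed residuals and `TS = PS * phi^(-1/2)` holds exactly
(asserted internally at 1e-8 relative tolerance).  Means use the raw
series (a trend should not count as instability but should not erase
abundance either); SDs use residuals with the n−1 denominator.  A
residual SD below 1e-10 of the series scale is treated as exactly zero,
so constant series are reported as degenerate (NaN + flag) rather than as
astronomically stable.  Compositional stability is `1 −` mean Bray–Curtis
dissimilarity between consecutive censuses on raw covers; census pairs
with nothing present in either census are skipped.  Each metric is
dispatched through the `FORMULAE` registry so an alternative
operationalisation (e.g. a covariance-based synchrony) can be swapped in
without touching callers.

Evenness on censuses with fewer than two taxa is excluded from the time
average rather than imputed as 0 or 1 — either substitution would bias
sparse high-shore tiles.  The convention (per-census J, then average) is
one of two defensible readings; computing J on time-averaged covers
instead is a one-line change in `summarise_tiles`.

## Mixed models

One model family serves the whole pipeline: Gaussian responses with
random intercepts for transect and station-in-transect, REML estimation
with both variance ratios profiled out of the criterion.  For the
paired-tile design the two grouping Gram matrices commute, so they are
jointly diagonalised once per fit and each criterion evaluation is
O(np) — this is what makes the resampling-heavy verification experiments
feasible on one CPU.  Fixed-effect t tests use Satterthwaite denominator
degrees of freedom computed from numerical derivatives of the REML
criterion; on reference fixtures the engine matches lme4/lmerTest to
four decimals in estimates, SEs, variance components and df (boundary
fits: df agree only loosely, as the approximation is ill-defined there;
estimates still match).  A Kenward-Roger-type (Kackar–Harville) adjusted
covariance is available as `df_method="kenward-roger"`; in our
calibration experiments it over-corrects (conservative), so Satterthwaite
remains the default.  Singular fits (a variance component at zero) are
retained and flagged, not refitted with a simplified structure.
Predictors are z-scored (n−1 SD) before interactions are formed;
responses are transformed per an explicit per-response policy (identity /
log / log1p / sqrt).  Marginal and conditional R² follow the Nakagawa
variance partition.

## Piecewise SEM

The causal hypothesis is a DAG over tile-level variables, declared in
YAML (`a -> b` edges, `a ~~ b` correlated errors, a grouping variable,
per-node transform/nesting options).  Each endogenous node gets a
component mixed model on its parents; standardised path coefficients are
`beta * sd(x)/sd(y)` on the analysis scale.  Directed separation is
tested over Shipley's union basis set: one claim per non-adjacent pair,
conditioning on the union of both nodes' parents, with the topologically
later node as response; pairs declared as correlated errors, and pairs of
two exogenous variables, carry no claim.  Claims combine into Fisher's
`C = -2 Σ ln p` with 2k df (p floored at 1e-16).  The basis set is
verified against brute-force graph d-separation on every DAG with up to
five nodes.

The default DAG has heterogeneity and emersion acting on five community
components (richness, dominant non-native barnacle, consumers, native
barnacles, ephemeral algae), which feed three stability mechanisms
(population stability, asynchrony, compositional stability), which feed
temporal stability.  Two structural choices deserve note.  First,
temporal stability receives only population stability and asynchrony
(plus emersion and native barnacles): `TS = PS * phi^(-1/2)` is an exact
identity, so a third mechanism conduit into TS could never show an
independent effect; compositional stability is instead a terminal
response with declared correlated errors to PS and TS.  Second,
population stability's parents include the community components that
mediate heterogeneity's indirect effects (richness, consumers, dominant,
ephemerals) — without them the direct refugia effect and the
richness/consumer-mediated suppression cancel *inside* one coefficient
and the model would report no refugia pathway at all.  Ratio-scale
responses (TS, PS) are log-transformed by default, which linearises the
decomposition identity.

Multigroup analysis: each edge's zone interaction is Wald-F-tested in the
pooled component model (which always carries the zone main effect, so
group mean differences cannot masquerade as path differences); edges with
interaction p < 0.05 are freed to per-zone estimates, the rest are
constrained to the pooled estimate.  Bootstrap replicates inherit the
base fit's free/constrained structure rather than re-deciding it.

Known calibration limits, measured and documented rather than hidden:
basis-set claims computed from one dataset are positively dependent, so
Fisher's C rejects a correct model somewhat above nominal even when every
claim p is exactly uniform (~7% instead of 5% for the default 11-node
DAG at n = 70 with exact tests; ~11% with the mixed-model machinery,
whose small-sample behaviour matches lme4/lmerTest exactly).  Users
comparing C against chi-squared at small n should treat marginal
rejections with caution.

## Cascading effects

The net effect of heterogeneity on a stability metric is the sum over all
simple directed chains of the product of standardised path coefficients,
a chain contributing only if every edge is significant at alpha (0.05 by
default, matching the convention that grey/non-significant paths carry no
cascade; `alpha = 1` disables masking, in which case the net effect
equals the SPC-matrix geometric series — a tested identity).  Uncertainty
comes from a nonparametric cluster bootstrap: stations are resampled with
replacement (within zone when the fit is multigroup), tile pairs travel
together, resampled stations are relabelled as distinct clusters, and the
percentile 95% interval of the recomputed net effect is reported.
Replicate fits use residual-df p values in the mask (the difference from
Satterthwaite is immaterial to a percentile interval and fits the
bootstrap inside a practical runtime).

## Problem sizes used in verification

The shipped verification experiments use the study-scale design (70
tiles, 11 censuses): 300 refits for Fisher's C calibration, 200
replicates each for SPC recovery and multigroup freeing, 100–150
bootstrap replicates per interval, and 1000 random matrices for the
decomposition identity; `scripts/acceptance.py` re-runs slightly smaller
versions of the same experiments.  These sizes give Monte-Carlo standard
errors comfortably inside the asserted tolerance bands.
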