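# Methods

## Carbon bookkeeping

The carbon module implements static density bookkeeping over a categorical
land-cover grid. Each class carries four pool densities in Mg/hm²
(aboveground biomass, belowground biomass, soil organic carbon, dead organic
matter); the class total is their sum. Densities are assumed constant in
time and space within a class — all storage change is driven by land-cover
transitions, never by within-class density dynamics. Units are fixed
throughout: areas in km², densities in Mg/hm², storage reported in 10⁴ Mg,
so storage = area × density / 100 (1 km² = 100 hm²).

Two entry points share one arithmetic path: `carbon_storage` (from a raster)
and `storage_from_area_table` (from a per-class area table); they agree
exactly by construction. The per-cell change map is expressed in Mg per cell
so its nansum equals the landscape storage delta with no unit juggling;
unchanged cells are exactly zero and cells nodata in either epoch are NaN.

Rounding: reported storage is rounded **half-up** (not banker's) to two
decimals at the reporting boundary only; all internal arithmetic keeps full
precision. Tests compare reported values at ±0.01 (one unit in the last
printed place).

The packaged Guizhou area table prints a 2050 forest area (9,012 km²) that
is inconsistent with both the constant simulated landscape total
(173,702 km²) and the 2050 forest storage implied by the forest density.
The loader therefore recovers forest-2050 by area conservation — the
landscape total minus the other five classes, 90,123 km² — which also
reproduces the published 2050 storage figures exactly. The raw printed value
is available with `reconcile=False`. Separately, the observed-epoch rasters
total 176,093/176,098 km² while the simulated epochs total 173,702 km²; the
package treats total area as whatever the input contains and makes no
adjustment.

## Transition accounting and agreement

The transition matrix is an exact cross-tabulation of two aligned class
grids scaled by cell area; cells nodata in **either** epoch are excluded
from both flow and agreement tallies so that row/column marginals stay
consistent with per-epoch class areas. Agreement is overall accuracy
(confusion trace over total) and Cohen's kappa with chance agreement from
the confusion marginals. Degenerate case: when both maps are constant
(p_e = 1), kappa is defined as 1 if they agree and 0 otherwise.

## Markov demand

The demand chain is the row-normalised observed transition matrix; classes
absent at the first epoch get identity rows. One step spans the calibration
interval (10 years when calibrated on a 2010→2020 pair), so a 2030 horizon
is one step past 2020 and 2050 is three. Demand vectors chain analytically
(v·Pⁿ) by default rather than being re-estimated from each simulated map;
`chain_from_map=True` switches to map-dependent chaining. Integer cell
targets come from largest-remainder rounding, which conserves the total
cell count exactly — the automaton's stopping condition can then be exact.

## Suitability learning (land-expansion analysis)

For each class k, positives are cells that were not k at the first epoch
and are k at the second; negatives are cells that were k at neither. Both
sides are subsampled at `sampling_rate` (default 0.01, intended for
~10⁶-cell provincial rasters; tests and fixtures use 1.0) from a seeded
permutation, so lower-rate samples nest within higher-rate ones. Negatives
are then balanced 1:1 against positives — balanced classes keep the forest's
vote fractions interpretable as development probabilities without
recalibration.

The learner is a random forest with 20 trees; `mtry` is 9 when at least
9 drivers are present, otherwise two-thirds of the driver count (minimum 1).
Driver layers are canonicalised to name order before fitting so results are
invariant to stack ordering; all randomness derives from the caller's seed,
and fitting is single-threaded so results are reproducible regardless of
available cores. Classes with fewer than 20 positives or negatives are
skipped with a uniform 0.5 surface and equal contributions (logged) —
too-rare expansion carries no learnable signal. Driver contributions are
normalised impurity importances.

Domain (neighborhood) weights default to each class's share of total
observed expansion area, (column sum − diagonal)/total expansion, summing
to 1. A published calibration vector can be passed through verbatim with
`basis="given"`; the packaged Guizhou vector (farmland 0.1470, forest
0.1841, grassland 0.0774, aquatic 0.0055, settlement 0.0117, other 0.0001)
sums to 0.4258, i.e. it was evidently not normalised to unit sum, so the
package stores given vectors exactly as supplied rather than renormalising.

## The patch-generating cellular automaton

Per round, for each cell of an over-demand class, candidate classes are
those the transition mask allows and that are still under demand. The
overall probability is OP_k = P_dev_k × Ω_k × w_k, with Ω_k the class-k
fraction of the 3×3 neighborhood (center excluded; truncated at edges;
nodata excluded from numerator and denominator). When Ω_k = 0 the cell may
nucleate a new patch: with probability `expansion_coeff × seed_fraction`
(0.5 × 0.05 by default, applied per round) it is offered
OP_k = P_dev_k × w_k × r with r ~ U(0,1). A candidate is drawn by roulette
wheel over the OP values and accepted only if its OP exceeds the global
threshold τ.

Published descriptions of this mechanism leave the threshold schedule and
roulette details open; the package fixes them as follows. τ starts at the
90th percentile of the first round's positive OP values — high enough that
early conversions happen at strongly supported cells — and decays by the
factor `patch_decay` (default 0.5) whenever a round converts fewer cells
than remain demanded, so allocation always terminates. Cells are visited in
a fresh seeded random permutation each round, removing scan-order bias.
Demand is approached monotonically: only over-demand classes release cells
and only under-demand classes gain them, which conserves the total count
each round and makes the default demand tolerance of 0 attainable; classes
at demand are frozen. Neighborhood surfaces are recomputed once per round,
not per conversion. Infeasible demand under the mask (an under-demand class
no surplus class may convert into) is rejected up front with the class
named.

For multi-horizon projections the automaton restarts from the previously
simulated map with a distinct derived seed per horizon.

## Entropy-weight scoring

Default behaviour: positive indicators standardise as (P−Pmin)/(Pmax−Pmin)
and negative ones as (Pmax−P)/(Pmax−Pmin); proportions, entropy and weights
follow the standard formulas with 0·ln 0 := 0; scores are weighted sums of
the **standardised** values, making them scale-free, bounded in [0, 1], and
monotone in every indicator. Some published presentations print the two
standardisation maps swapped and compute the final score on raw values;
those literal variants are preserved behind `form="as_printed"` and
`basis="as_printed"` for comparability, but the defaults follow the
orientation semantics ("larger is better" for a positive indicator) because
the swapped equations contradict them and the raw-value score is
scale-dependent. Edge conventions, all logged: constant columns standardise
to 0.5; an all-zero column gets entropy 1 (hence weight 0); if every
indicator has entropy 1, weights fall back to equal. Score bands for
mapping use quantile classification with 4 bins.

## Synthetic landscapes

The generator exists to give every stage a fully known truth. Class maps:
a Gaussian random field smoothed at `autocorrelation_scale` and cut at
class-fraction quantiles — realised shares are exact up to integer rounding
and spatial clustering grows with the scale. Drivers: smoothed unit-variance
noise plus planted per-class mean shifts (shift ≈ 2 gives separable
signal, 0 gives a null driver). Evolution: exact per-pair conversion
counts, placed at the top-affinity source cells (seeded shuffle for
tie-breaks; optional stochastic placement for stress tests), each cell
converting at most once — so the planted transition matrix is recovered
exactly. The default two-epoch fixture uses provincial class shares and
flow magnitudes scaled from the observed decade of change (roughly 0.3–1%
of the landscape per major flow).

What this does **not** emulate: real karst geomorphology, correlated driver
fields (drivers are mutually independent by construction), measurement and
classification error, or multi-decadal non-stationarity. Passing tests
therefore demonstrate that the algorithms recover known structure under
clean conditions, not that a particular real-world calibration is accurate;
the published validation of a real-raster simulation (kappa 0.76, overall
accuracy 0.83) depends on data that are not redistributable and is treated
as context, not as a target.

## Problem sizes and runtime choices

Tests run the automaton and suitability benchmarks on 200×200-cell
landscapes (40,000 cells) with 5 automaton seeds, and planted-driver
recovery on 20 replicates of 60×60 landscapes — sizes at which every
benchmark is stable across seeds while the full suite stays interactive.
The demand-matched random-allocation baseline reallocates the same surplus
cells uniformly at random; the automaton's kappa against the known truth
exceeds it systematically (≈0.92 vs ≈0.90 on the default fixture — both
high because ~95% of cells are unchanged over one step, so the margin, not
the level, is the informative part).

## Known limitations

- Single-scenario simulation only: no ecological-redline or policy
  constraint scenarios beyond the 0/1 transition mask.
- No reprojection or resampling; all inputs must be pre-aligned on one
  grid (`align_check` enforces this).
- Carbon densities are static; no valuation, sequestration-rate, or
  density-interpolation options.
- The automaton recomputes neighborhoods per round rather than per
  conversion; with very large single-round allocations patch shapes can be
  slightly coarser than a per-conversion update would give.
- Second-level (25-type) land-cover codes are out of scope; inputs must be
  aggregated to the six first-level classes.
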