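# Methods

## Radiocarbon calibration

A determination (age *a* ± σ in ¹⁴C yr BP) is calibrated against a
curve μ(t), σ_c(t) resampled to a 1-year calendar grid by linear
interpolation. The posterior mass at calendar year *t* is proportional
to the normal density of *a* − μ(t) with variance σ² + σ_c(t)², then
normalized to sum to one; tails holding less than 10⁻⁶ of cumulative
mass are truncated. This is the standard intercept-free probabilistic
calibration; the 1-year grid is an implementation choice, fine enough
that no downstream statistic changes at 0.1-yr resolution.

A single Southern Hemisphere curve is applied to all records, including
those north of the equator — the inter-hemispheric offset (~15 ¹⁴C yr)
is far below the lab errors retained (up to 200 yr). Marine reservoir
corrections and mixed curves are out of scope.

The **median** is defined by accumulating mass from the older end and
reporting the year where it first reaches 0.5 (ties resolve to the
older year). "Earliest" — both per site and per spatial bin — means the
largest median calibrated age, with ties broken by smaller lab error,
then input order. Records with σ > 200 yr or flagged unreliable are
dropped before any analysis; reliability is an input column, not
re-adjudicated by the software. Competing chronologies for the same
culture are expressed as different input tables.

## Space–time regression

Distances are great circles (haversine, R = 6371 km) from a candidate
origin. Sites (already earliest-per-site) are thinned to the earliest
per half-open distance bin [k·w, (k+1)·w); a fit requires at least 5
surviving sites. Bin widths of 100–500 km are scanned in 100-km steps.

The fit is reduced major axis: r is the Pearson correlation, slope =
sign(r)·s_y/s_x, intercept = ȳ − slope·x̄. RMA is preferred over OLS
because both variables carry error — dates through calibration, and
straight-line distance because the travelled path was not straight.

Calibration uncertainty is propagated by bootstrap: 999 iterations,
each drawing one calendar year per site from its calibrated density and
refitting. Reported summaries are means and 2.5/97.5 percentiles across
iterations. Front speed is −1/slope computed per iteration; iterations
with non-negative slope are excluded from the speed summary and
counted. Significance is the mean across iterations of the two-sided
t-test p-value of r (threshold 0.05). The per-iteration mean p-value
was chosen over a single test on the mean draw: it reflects the
calibration uncertainty the bootstrap exists to propagate.

Origin scanning refits every site × bin-width combination passing the
5-site rule and flags the significant result with maximal |r̄|.

Caveat: with error in the year draws, RMA's slope magnitude is inflated
by the ratio of total to structural variation in the dates, so speed is
biased low by roughly ½(σ_eff/s_t)², where σ_eff (~85 yr: lab error
plus the bootstrap draw) is the effective date noise and s_t the spread
of true arrival times. At 0.5–1 km yr⁻¹ over 2000 km (2000–3400 yr of
time depth) the bias is under 1% and the 95% CI covers the true speed
in ~95–96% of replicates. At 2 km yr⁻¹ the same 2000 km span only
spans 1000 yr, the bias grows to ~3% and measured coverage sits at
~89% — the nominal boundary. Fast expansions dated over short time
depths are where this estimator is weakest; the effect is a property of
RMA under date noise, not of the implementation.

## Model space

The simulator runs on a square equal-area grid of 10 × 10 km cells.
Input rasters must already be projected with square cells (ESRI ASCII
dialect; NODATA honored); the package validates but does not reproject.
Closed-form spherical projections are provided for mapping site
coordinates onto a grid: Lambert azimuthal equal-area (used for
synthetic radial expansions — radial distances from the center match
great circles to <0.2% within ~2000 km) and Albers equal-area conic for
continental grids. Each cell carries a suitability in [0, 1] — in a
real analysis the output of a species-distribution model, taken as an
input here — and is settleable where suitability meets a per-culture
threshold. A Miami-model net-primary-productivity helper
(min of a temperature and a precipitation saturation term, both
asymptoting at 3000 g m⁻² yr⁻¹) is included for building synthetic
covariates; niche modelling itself is out of scope.

## The agent-based model

Agents are villages; one step is one year, counted down from a start
date (sim BP) to 500 sim BP. Parameters and their ranges, from the
ethnography of tropical-forest farmers:

| parameter | default | range | unit |
|---|---|---|---|
| growth rate a | 0.025 | fixed | yr⁻¹ |
| max density K\* | 60 | 20–100 | persons / 100 km² cell |
| catchment radius | 20 | 10–30 | km |
| fission threshold | 150 | 50–300 | persons |
| leap distance | 0 | 0 or 150–250 | km |
| permanence | 20 | 10–30 | yr |

Each year every active village, in seeded random order:

1. **Growth**: N ← N(1+a). Over its ceiling (K\* × claimed cells) it
   claims the best unclaimed settleable cell within its catchment,
   raising the ceiling; claiming is exclusive, one cell per
   over-ceiling year, ties broken by seeded draw. Claiming does not cut
   the population even if the new ceiling is still exceeded — territory
   catches up at one cell per year; only saturation (no claimable cell)
   clamps the population back to the ceiling.
2. **Fission**: at or above the threshold, and with at most 6 neighbors
   (homes within 2× catchment — the hexagonal-packing nearest-neighbor
   distance for non-overlapping territories), a daughter takes half the
   population and settles the best free cell in the ring just beyond
   the catchment (distance in (catchment, catchment + 10 km]). Failing
   that, a leapfrog daughter may settle in the annulus leap ± 10 km,
   but only onto a cell strictly more suitable than home. With no
   destination the population simply keeps growing past the threshold.
3. **Relocation**: after more than `permanence` years in place, the
   village searches the same ring (then the leap annulus), releases all
   claimed cells and moves; its residence clock resets. Daughters start
   with a fresh clock.

The founding village is created at the fission threshold, so the
expansion launches on the first step. Villages clamped at their ceiling
with no adjacent or leap destination become inactive (and never
reactivate): the front carries all activity. Short-range (<1–2 km)
residential moves are below grid resolution and not modelled; so are
warfare, hierarchy and trade.

**Arrival raster.** A cell's arrival is the year it is *first occupied*
— settled as a home or claimed as catchment territory — and is never
overwritten; fitness concerns first colonization. Recording claims, not
just homes, matters: only about a quarter of cells ever host a home
near front passage, and scoring against home settlements alone would
systematically lag the colonization front by centuries.

Emergent behavior (measured by the test suite and acceptance script):
aggregate population on a uniform landscape is sigmoid (slow start from
frequent fission, exponential middle, plateau near 0.8 of the K\*
capacity — clamping and relocation churn keep it below the hard bound);
the front radius grows linearly in time (R² > 0.99 on a 200×200 grid)
at an emergent speed of ~0.75/0.95/1.2 km yr⁻¹ for catchments of
10/20/30 km at the default parameters; territory claims stay pairwise
disjoint; with leapfrogging disabled no occupied cell is ever farther
than catchment + 10 km from previously occupied land.

Internally the grid is padded and flat-indexed, with an incrementally
maintained free-cell mask and neighbor-count field; within a village's
turn a failed neighborhood search cannot succeed later in that turn, so
negative results are reused. None of this affects semantics.

## Fitness

Evaluation sites are the earliest date per spatial bin (the bin width
that maximized |r| in the regression), mapped to grid cells. Each site
scores its calibrated density *normalized to peak 1* at the simulated
arrival year of its cell — zero if unreached or outside the support —
and fitness is the mean over sites. Peak normalization is what makes a
perfect score of 1 attainable (arrival at every site's modal year);
sum-normalized densities could never reach it. Unreached sites score 0
rather than being excluded, consistent with "no match" meaning zero.
Densities are evaluated at the exact integer year, no smoothing.

## Genetic algorithm

Genomes are parameter sets (growth rate is not a gene). Population 100;
each generation the top 40 reproduce; offspring arise from parents
paired uniformly at random with replacement, single-point crossover
with probability 0.8 (cut strictly inside the fixed gene order), then
per-gene mutation with probability 0.2 (uniform redraw); the 5 best are
copied unchanged, keeping the population at 100 for 20 generations.
The leap gene is drawn as 0 with probability ½ and otherwise uniform in
150–250 km, at initialization and on mutation. Because the simulator is
stochastic, a genome's fitness is a single-run draw and identical
genomes are re-evaluated, not cached — selection sees fresh noise, and
reported best fitnesses carry that noise. Fixed-catchment runs (10, 20
or 30 km), used to probe the equifinality between catchment area and
K\*, are implemented by pinning the gene's range to a single value,
which is behaviorally identical to removing it from the genome.

## Synthetic data and what validation does (not) show

The generator is the calibration model run backwards: sites are placed
at seeded random bearings and distances from an origin (uniform in
distance by default so every regression bin is populated; uniform in
area optionally), the true arrival at distance d is t₀ − d/v, and the
recorded age is the curve's ¹⁴C age at that year plus Normal(0, σ_lab),
rounded. The identity "toy" curve (¹⁴C age = calendar age, zero curve
error) makes analytic checks exact; with a real curve the inverse is
evaluated at the true calendar year. Default conditions describe a
realistic late Holocene continental expansion: start 4000 cal BP,
1 km yr⁻¹, 40 sites to 2000 km, 60-yr lab errors; validation also uses
0.5 and 2 km yr⁻¹ with the maximum distance capped so the front stays
inside the curve and above 500 cal BP.

Validation problem sizes — 100 replicates per speed for CI coverage, a
200×200-cell landscape over 2000 years for the simulator properties,
10 seeds for GA convergence — were chosen to give stable rates while
keeping the whole battery under a minute.

What the synthetic record does *not* emulate: research and taphonomic
biases in where dates exist, multi-component sites with long
occupations, irregular multimodal calibrated densities (the toy curve
has no wiggles), cost-distance geography, and heterogeneous real
landscapes. Passing recovery tests therefore shows the estimators are
consistent under the model's own assumptions, not that any particular
archaeological dataset satisfies them. Reproducing the published
regression tables requires the original compiled date table and the
ShCal13 curve (see README); those tests report exactly what is missing
when the files are absent.

## Numerical choices and edge cases

- RMA requires ≥3 points and nonzero variance in both variables;
  degenerate inputs raise rather than return NaN.
- Bootstrap CIs are percentile (2.5/97.5), not normal-theory.
- The bin rule is half-open; the origin site sits in bin 0 at distance 0.
- Curve files may be comma- or whitespace-separated, ascending or
  descending; non-monotone grids are format errors.
- Rasters with cell sizes above 1000 are interpreted as meters and
  converted to km.
- All randomness flows through `numpy.random.Generator`; every public
  entry point takes a seed or generator, and equal seeds give bitwise
  identical runs.
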