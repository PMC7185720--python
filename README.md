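# demicwave

Tools for testing whether an archaeological expansion — the spread of a
ceramic tradition across tropical South America, say — can be explained
as **demic diffusion**: a population of farming villages growing,
fissioning and migrating outward as a wave of advance, rather than
practices spreading between resident peoples.

The package is aimed at archaeologists and quantitative
palaeodemographers working with compilations of radiocarbon dates. It
couples three layers:

1. **Space–time regression.** Under a constant-rate expansion from an
   origin, first-arrival dates fall linearly with great-circle distance
   *d* from that origin: *t(d) = t₀ − d/v*. Calibrated ¹⁴C dates are
   thinned to the earliest per site and per distance bin, and a
   **reduced major axis** (RMA) line — slope ±s_y/s_x, symmetric in the
   errors of both variables — is fitted 999 times, each time drawing a
   single calendar year per site from its calibrated probability
   distribution. The intercept estimates the start date *t₀* (cal BP),
   −1/slope the front speed *v* (km yr⁻¹), with bootstrap 95% intervals.
   Scanning all sites as candidate origins locates the most likely
   cradle of the expansion.
2. **Agent-based simulation.** Villages on an equal-area 10-km grid
   grow at a fixed 2.5% yr⁻¹, claim catchment territory up to a density
   ceiling K\*, fission at a population threshold into the best free
   cell beyond their catchment (or leapfrog 150–250 km to better land),
   and relocate after a maximum permanence time. One step is one year;
   the run ends at 500 sim BP and yields a first-arrival raster over a
   habitat-suitability landscape.
3. **Evaluation and calibration.** A simulated expansion is scored in
   [0, 1] against the dated record: each earliest-per-bin site
   contributes its peak-normalized calibrated density evaluated at the
   simulated arrival year of its cell. A genetic algorithm (100
   genomes, 40 parents, crossover 0.8, mutation 0.2, 5 elites, 20
   generations) searches the demographic parameter space for the
   best-fitting simulation.

A synthetic-data layer generates landscapes, constant-speed radial
expansions and back-calibrated date tables with known ground truth, so
every stage is validated by parameter recovery.

## Worked example

Generate a synthetic expansion (1.0 km yr⁻¹, starting 4000 cal BP, 40
sites with 60-yr lab errors) and recover its parameters:

```sh
demicwave synth dates --spec spec.json --out dates.csv
demicwave regress --dates dates.csv --curve toy.14c \
    --origin S000 --width 100 --iters 999 --seed 7
```

```
origin_site  bin_width_km  n_points  start_cal_bp    start_lo    start_hi  speed_km_yr  speed_lo  speed_hi    r_mean   p_mean  significant
       S000         100.0        18   4011.132678 3954.276767 4066.196263     0.995846    0.9531  1.045216 -0.993833  1.0e-15         True
```

The 18 earliest-per-bin sites give a mean correlation of −0.99; the
start date is recovered as 4011 cal BP (95% CI 3954–4066, truth 4000)
and the front speed as 0.996 km yr⁻¹ (CI 0.953–1.045, truth 1.0).

Other subcommands: `scan` (origin search over all sites and bin
widths), `simulate` (one agent-based run to an arrival raster),
`fitness` (score a raster against the dates), `ga` (genetic-algorithm
calibration), `synth` (synthetic landscapes/dates/rasters). The same
functionality is available as a library; see `docs/methods.md` for the
model description.

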