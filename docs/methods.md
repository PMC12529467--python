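# Methods

This note documents the model that `fxsim` implements, the defaults that
matter, what the synthetic data generator does and does not emulate, and the
design choices made where the design was genuinely open.

## Scope and intent

`fxsim` is a desk-scale reimplementation of a fire-exclusion-zone (Fx)
simulation experiment: it reproduces the *experimental design* (factorial
structure, scenario generators, response metrics, statistical attribution)
and the *directional mechanisms* (seed-source protection, dispersal
limitation, climate-filtered establishment) of landscape-scale studies run
with full individual-based forest models. It does not attempt tree-level
physiology, real terrain, or downscaled GCM climate, so its absolute
densities and burned areas are not comparable to any particular real
landscape; its scenario *contrasts* are the object of interest.

## Landscape generator

A `GridSpec` (default in experiments: 100 × 100 cells of 100 m; 1-ha cells)
carries all rasters. Elevation is a linear north–south gradient spanning
1600–2900 m a.s.l. plus a smoothed Gaussian random field (SD 120 m). The
stockable (potentially forested) mask thresholds an independent smoothed
field at the quantile giving a target stockable fraction (default 0.9).

Species occupy elevation bands with soft (logistic, 150-m scale) overlap
inside hard limits: Douglas-fir below 2150 m, lodgepole pine 1700–2650 m,
spruce–fir above 2350 m. The hard limits make zonation assertions exact by
construction; the soft interiors create mixed ecotones. Lodgepole is split
into serotinous and non-serotinous variants by a spatially coherent
serotiny fraction (0.15–0.85). Mature density is 250 trees/ha × band weight
× lognormal noise (σ = 0.3).

Stand ages mix a mature mosaic (uniform 60–300 yr) with a young,
recently-burned component: a configurable fraction (default 10 %) of
stockable cells drawn i.i.d. with stand age and time-since-fire uniform on
[0, 40) yr. These cells play the role of recent burn perimeters: they are
excluded from Fx placement (Fx zones protect live seed sources) and carry
regenerating cohorts of the locally dominant species instead of mature
trees. Serotinous canopy seed banks initialize as fecundity × density ×
min(stand age − maturity, 30) seeds/ha.

What the generator does **not** emulate: real topographic structure
(aspect, drainage), soil and water-balance heterogeneity, historically
accurate fire perimeters, or observed stand-structure covariances. Tests
passing on these landscapes therefore demonstrate internal consistency of
the mechanisms and design, not predictive skill for any real place.

## Climate generator

Each of the four scenarios (warm-wet, hot-wet, warm-dry, hot-dry) is an
annual summer series for 2021–2100: a linear trend plus AR(1) noise
(coefficient 0.3; SDs 0.7 °C and 2.0 cm — implementation defaults, not
taken from any projection). Scenario targets are the midpoints of the
projected end-of-century ranges: warming +4.15 °C (warm) or +6.7 °C (hot),
summer precipitation +2.4 cm (wet) or −2.1 cm (dry), defined as last-decade
mean minus first-decade mean. The AR(1) noise is linearly detrended through
its first- and last-decade means so that the realized decadal delta equals
the target for every seed; with zero noise the series is exactly linear.

The aridity index is standardized temperature minus standardized
precipitation, standardized against **fixed reference constants** (13 °C /
1.5 °C; 12 cm / 2.5 cm) shared by all scenarios. A within-series z-score
would erase the between-scenario contrast that the fire regime must see;
fixed-baseline standardization keeps hot-dry late-century aridity (≈ 4.7)
well above warm-wet (≈ 0.9). Summer temperature is lapsed to cell elevation
at 0.65 °C / 100 m around a 2300-m reference, which maintains elevational
zonation dynamically (upslope niches stay cooler longer).

## Fx scenario construction

*Dispersed* masks select each stockable cell i.i.d. with probability equal
to the amount (random-map NLM). *Clumped* masks threshold a fractional
Brownian motion surface, synthesized spectrally with power-spectrum
exponent β = 2H + 2, H = 2 − fractal dimension (fd 0.9 ⇒ β = 4.2, strong
autocorrelation). Binarization is by exact quantile: precisely
⌈amount × n_stockable⌉ cells are selected, ties broken by cell index, so
nominal coverage is exact to one cell. Only the autocorrelation ordering
(clumped ≫ dispersed) is consequential downstream, and that ordering is
insensitive to the exact Hurst convention.

Both NLM kinds are generated on the full rectangle and then constrained to
stockable ∩ mature (stand age ≥ 60 yr) ∩ not recently burned
(time-since-fire ≥ 40 yr); realized coverage below nominal is recorded in
the scenario's provenance.

The *operational* delineation intersects vulnerable-species density
(fir + spruce + Douglas-fir ≥ 50 trees/ha), containment likelihood ≥ 0.20,
and mature forest, always adding three developed areas. 8-neighbor patches
below 55 ha are dropped; if coverage exceeds the 30 % budget, whole patches
are dropped in ascending order of a priority score (mean vulnerable density
× containment — an invented rule; no drop rule is prescribed when
candidates exceed the budget). If whole-patch drops cannot reach the budget
(one giant candidate patch), the mask is carved along its weakest cells
(lowest vulnerable × containment), splitting it into defensible sub-patches
— the raster analogue of cutting fuel breaks — and sub-minimum fragments
are dropped. The synthetic containment product is a cubed smoothed field
(high containment scarce) elevated along a sinusoidal road/river corridor;
its correlation length is a free choice, as no grain is prescribed for the
real product.

## Fire regime and spread

Annual large-fire (≥ 400 ha) counts are Poisson with rate
λ_L(a) = λ₀ exp(b·a) in the aridity index a; size caps are truncated Pareto
(α = 1.8) on [400 ha, min(0.3 × stockable, 4000 ha)]. Small-fire counts are
Poisson with a rate proportional to stockable area (0.09 per 1000 ha per
yr) and log-uniform caps on [1, 400) ha. λ₀ and b are solved in closed form
from two anchors: expected burn = 1.7 % of stockable area per year at the
warm-wet mean aridity, and 3.4× that at the hot-dry late-century (last 25
yr) mean — the ratio of the hottest-driest to the mildest scenario's burn
levels. Caps are treated as binding maxima; realized sizes can fall short
when spread stalls.

Spread is a stochastic cellular automaton: each front cell attempts each of
its 8 neighbors once with p = p₀ · f_fuel · f_slope · f_wind clipped to
[0, 1], p₀ = 0.55. f_fuel = (0.2 + 0.8(1 − e^(−tsf/25))) ·
(0.3 + 0.7 min(density/150, 1)) recovers with time-since-fire and
saturates with stand density (these logistic/saturating surrogates stand in
for a fuel model that is not specified at this level); f_slope is linear in
the elevation difference (clipped 0.2–1.6); f_wind = exp(0.15 · speed ·
cos Δθ) with one wind draw per event (uniform direction, lognormal speed).
Fx cells and non-stockable cells never ignite: exclusion is hard, and fires
flow around Fx zones. Ignitions are drawn uniformly over stockable, non-Fx
cells (equivalent to redrawing ignitions that land in Fx, keeping fire
frequency comparable across scenarios). Within a year, cells already burned
cannot reburn (fuel consumed), which keeps the area-burned accounting exact
when fires overlap. Severity rises with fuel, falls with the resister share
of the canopy, and is clipped to [0.05, 1]; severity ≥ 0.5 is
stand-replacing and resets stand age and time-since-fire.

## Regeneration

Seed rain for non-serotinous species convolves source strength (fecundity ×
mature density × deterministic mast cycle, on cells at or past maturity age
— surviving resister canopies keep producing after a fire resets stand age)
with a discrete isotropic 2Dt kernel (shape p = 2; scale u = 2·mean/π so
the kernel's mean distance equals the species' `kernel_scale`), truncated
at 5× the mean distance and renormalized to sum to 1; the boundary is
absorbing. Kernel-scale ordering fir 30 < lodgepole 60 < spruce 80 <
Douglas-fir 100 m encodes fir's short-distance dispersal; the numeric
values are config-exposed defaults. Serotinous seed supply is only released
by fire (in `apply_fire_effects`), if the stand has reached maturity.

Establishment multiplies a Gaussian thermal envelope on the
elevation-lapsed summer temperature, an exponential drought penalty
exp(−s_d · max(a, 0)), and a light factor (1 within 5 yr of fire; the
species' shade factor under ≥ 50 trees/ha of canopy; 0.7 otherwise), plus a
lognormal year effect (σ = 0.2). Establishment ratio 0.1 and an
8000 /ha cohort cap keep densities in the range observed for these forests
(tens to thousands of seedlings/ha). Envelope parameters encode the
field-known ordering: spruce is the most temperature- and drought-sensitive
(T_opt 10 °C, width 2.5, s_d 1.3), fir intermediate, lodgepole broad, and
Douglas-fir warm-adapted (T_opt 16 °C) so warming favors it. Fecundities
(600–1200 seeds/tree/yr) are order-of-magnitude defaults.

Cohorts are per-species rasters of density, age, and height; a cohort's age
counts full years since establishment. Cohorts grow at fixed height rates
and graduate at 4 m; when several species' cohorts co-occur, the first to
reach 4 m wins the cell and competing cohorts are removed (a
`loser_retention` option keeps a fraction). Graduating stems join the
mature layer with 25 % self-thinning, capped at 2000 stems/ha entering.

## Metrics and statistics

* Area burned per period: early fire years 2021–2045, late 2071–2095;
  replicate means, then group mean ± SE (SD/√n; n = 1 reports SE 0 with a
  degeneracy flag).
* In-patch regeneration: a fire patch is the set of burned cells of one
  fire event; density is read lag = 5 yr after the fire (lag 15 as the
  robustness option) counting cohorts of age ≤ lag (new postfire
  establishment, not pre-fire survivors); fires whose observation year
  falls outside the simulation are excluded and counted. Means across fires
  are area-weighted by default (fire-weighted optional; the choice is not
  prescribed). Fires are assigned to windows by ignition year.
* Difference maps: per-cell replicate-mean operational minus reference at
  2100; |Δ| ≤ 100 seedlings/ha is "none", both-absent is "absent",
  otherwise more/less by sign; the display transform is
  sign(Δ)·log₁₀|Δ|. Distance to Fx is the Euclidean distance transform,
  cell center to center (edge-of-patch distance differs by ≤ cell/√2); a
  zone-of-influence summary reports the 75th percentile distance of "more"
  cells.
* Statistics: responses are log₁₀(x + 1)-transformed. The two-way ANOVA
  (amount × configuration, interaction included and reported separately)
  uses Type II sums of squares — identical to Type I/III on the balanced
  design — pooling climates (a `block_climate` option adds climate
  additively; pooling vs. blocking is not prescribed). Per-climate OLS uses
  ordinal-numeric amount (0/0.1/0.3/0.5) plus a dispersed indicator, with a
  categorical-amount option. Interpretation is by F/t magnitudes and
  adjusted R², not p-value thresholds. Constant responses short-circuit to
  t = 0 rather than 0/0.

## Orchestration and problem sizes

Sub-seeds for every stream (landscape, NLM, fire, regeneration) derive from
one master seed by a CRC32 counter hash of the stream name, so any run is
independently reproducible. One NLM per amount × configuration in the
factorial (the robustness set varies 10 NLMs × 2 configurations × 10 fire
histories in hot-dry climate). Fire seeds are paired across scenarios
within a replicate (same ignition sequence meets different landscapes),
which sharpens scenario contrasts; an `independent_fires` flag decouples
them. Runs are resumable: per-run metric rows are cached as JSON keyed by
the run's seeds.

Problem sizes: the `ci` preset uses a 100 × 100 grid (10,000 ha) with 5
replicates (140 factorial runs, ~2 s per 80-yr run); the `full` preset
uses 200 × 200 with 20 replicates (560 runs). The desk-scale grid is
commensurate with, but smaller than, the ~57,000-ha landscapes such
experiments target, and a single 100-m resolution replaces nested
2/20/100-m grids; kernels and spread are parameterized in meters, so
resolution is configurable.

## Numerical choices and degenerate inputs

Kernel weights sum to 1 within the truncation radius (error < 1e−6 by
construction); quantile binarization breaks ties by cell index; fBm
synthesis rejects a degenerate constant surface; the spread front caps the
burned count exactly (excess newly-ignited cells are dropped in flattened
cell order); empty fire lists, empty manifests, empty candidate sets, and
empty difference classes all return empty results with warnings rather
than errors; distance to an empty Fx mask is an error (undefined).

## Known limitations

No physiological growth, light interception, or water balance; no
individual trees; no bark-beetle or wind disturbance; no microclimate
buffering by mature canopies (benefits of Fx zones are therefore likely
understated); no management-cost accounting; aspen and whitebark pine are
out of scope. Mature-tree background mortality is omitted, so seed sources
persist unless burned. The regime calibration anchors expectations, not
realizations: realized burn falls below expectation when fuel or landscape
structure limits spread, and the hot-dry/warm-wet realized ratio is
reported by the experiment rather than imposed.
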