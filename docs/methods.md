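# Methods

This note documents the models implemented in `careseek`, the choices
made where the method is genuinely open, and what the synthetic-data
generator does and does not emulate.

## Friction surface

Every raster layer shares one planar grid (metres; default 1 km cells).
Each cell carries a base speed (km/h) and a transport mode:

| source              | class                     | km/h | mode      |
|---------------------|---------------------------|------|-----------|
| land cover          | tree cover (broadleaved / needleleaved) | 5 | walking |
|                     | tree cover, other         | 2    | walking   |
|                     | shrub                     | 5    | walking   |
|                     | herbaceous                | 3    | walking   |
|                     | sparse herbaceous         | 4    | walking   |
|                     | cultivated                | 5    | walking   |
|                     | bare / desert             | 2    | walking   |
|                     | water                     | 0    | barrier   |
| roads               | primary                   | 80   | motorised |
|                     | secondary                 | 60   | motorised |
|                     | tertiary                  | 10   | cycling   |
| rivers              | (major rivers only)       | 0    | barrier   |

Precedence within a cell is primary > secondary > tertiary road > land
cover. Rivers are absolute barriers **unless** a road crosses the same
cell (bridge assumption — road networks plainly cross rivers). Polylines
are rasterized with the all-touched convention (a cell is a road/river
cell if the line intersects it), which is deterministic and
resolution-honest. There is no mode-switching penalty at walk→road
transitions; a journey simply uses the speed of each cell it traverses.

### Slope

Walking speed on slope θ (degrees) follows the hiking function
V(θ) = 6·exp(−3.5·|tan θ + 0.05|), maximal (6 km/h) at a gentle downhill
of tan θ = −0.05 and ≈ 5.04 km/h on flat ground. Because the formula
takes |·|, traversal is symmetric uphill/downhill, so slope can be
applied per *edge* rather than per pixel without loss: each edge's slope
is arctan(|Δelevation| / distance) between the two cell centres, and the
multiplier V(θ)/V(0) scales the effective speed of walking and cycling
cells only (motorised travel ignores slope). Keeping slope out of the
stored surface means the tabulated speeds stay exactly reproducible on
flat terrain, and any DEM resolution can be supplied. A per-pixel
alternative was considered and rejected: it bakes one DEM's slopes into
the friction layer and makes the table values unrecoverable.

## Travel-time accumulation

The non-barrier cells form an 8-connected graph; orthogonal edges span
`cell_size`, diagonal edges `cell_size·√2` (the standard raster
cost-distance convention). Edge time in minutes is `60·d/v` with `v` the
**harmonic mean** of the two endpoint effective speeds — each cell
contributes half the edge length at its own speed, so the harmonic mean
is the time-correct average (an arithmetic mean would underestimate the
time across slow/fast boundaries). Multi-source Dijkstra from all
facility cells yields per cell the minutes to, and identity of, the
least-cost facility. Implementation notes:

- unreached cells carry **+inf**, never a nodata zero — a zero would
  silently enrol them in catchments;
- exact ties in arrival time are broken toward the **lowest facility
  id** (heap entries are ordered `(time, facility_id, node)`), making the
  allocation raster deterministic;
- correctness is tested against an independently coded Bellman–Ford
  relaxation oracle on random instances, to 1e-9 minutes (the two
  algorithms sum identical edge weights in different orders, so exact
  bitwise equality is not meaningful for floats).

## Distance-decay model

Attendance is modelled as Y(x) = C/(1 + e^((A−x)/B)) on transformed
travel time x. Choices that matter:

- **Transform: log₁₀ of minutes by default** (natural log and identity
  are available and recorded in the fitted object). On the log₁₀ scale
  the reference coefficients (C = 0.766, A = 3.736, B = −0.609) give
  p(180 min) ≈ 0.704 — attendance stays high out to three hours and
  decays thereafter, the behaviour the model is meant to capture.
- **Floor t ≥ 1 minute** before the log: households in a facility's own
  cell have near-zero but positive access time; the floor keeps the
  transform finite and the prediction at the floor just below C.
- **Grouped least squares, not binomial likelihood.** Outcomes are
  grouped into 15 quantile bins of x (equal counts ±1; empty bins
  dropped; configurable) and the curve is fitted to the bin proportions
  by unweighted nonlinear least squares. With ~equal bin sizes the
  information loss versus the raw Bernoulli likelihood is negligible,
  and grouped residuals give the familiar small SSR / RSE diagnostics.
  A binomial-likelihood fit is easy to add but is not the reference
  path.
- **Multi-start initialisation**: C₀ = max p̂ (clipped to (0, 1]),
  A₀ = median x̄, B₀ ∈ {±0.5, ±1}, best SSR wins; C is bounded in
  (0, 1]. Non-convergence from every start raises with diagnostics; a
  monotone-*increasing* attendance pattern still returns a fit but is
  flagged and warned about.
- **Uncertainty**: per-coefficient standard errors from the asymptotic
  covariance (JᵀJ)⁻¹·s² with s² = SSR/(n_bins − 3); two-sided p-values
  from the t distribution on n_bins − 3 degrees of freedom.
- With C fixed at 1 the fit reproduces an ordinary two-parameter
  logistic (tested against an independent `curve_fit`).

The probability surface evaluates the fitted curve at every cell;
unreached cells take the infinite-time limit, which is 0 for a decaying
model (B < 0).

### Identifiability caveat

When observed travel times sit well below the curve's inflection
(10^A minutes), the data cover only the upper shoulder and A and B are
weakly identified per sample even at large n, while C remains tightly
pinned by the near-facility bins; estimates are median-unbiased across
replicates. Users fitting surveys where nearly everyone lives within a
few hours of a facility should expect exactly this pattern (it is
visible in the standard errors) and should not over-interpret A and B
individually.

## Catchments and burden

A cell belongs to the catchment of its allocated facility iff its travel
time is ≤ the threshold (default 180 minutes, where the decay model's
predicted attendance begins to fall steeply); other cells are "outside".
Burden arithmetic per cell:

    children = population × under-five fraction(region)
    fevers   = children × fever prevalence(region)   (one episode per child per period)
    attendees = fevers × Y(travel time);  non-attendees = fevers − attendees

Prevalence is applied uniformly within a region, which masks fine-scale
heterogeneity; a per-catchment prevalence hook exists but is off by
default. Probability is evaluated at **every** cell including outside
catchments (the beyond-threshold stratum still has some expected
attendees), while "children within a catchment" counts only cells inside
the threshold. Counts stay real-valued internally; percentages are
rounded half-away-from-zero to one decimal only at report time, so
attendees + non-attendees = fevers holds exactly in every stratum.
Binomial survey proportions get Wald intervals (e.g. 401 of 2,283 →
17.6% [16.0, 19.1]); uncertainty from the decay fit is *not* propagated
into burden totals.

## Synthetic-data generator

The generator produces internally consistent inputs with the statistical
structure the analysis assumes, sized like a national malaria indicator
survey: 120 clusters × ~25 households, nine regions with fever
prevalence spanning 0.07–0.28, under-five fraction 0.165 everywhere,
1 km cells, and a true decay model (default C = 0.766, A = 3.736,
B = −0.609, log₁₀ minutes) used to draw attendance. Specifics:

- **DEM**: Gaussian-smoothed white noise (σ = 3 cells), scaled to a
  relief amplitude (default 300 m s.d.); amplitude 0 gives flat terrain.
- **Land cover**: quantile-thresholded smoothed noise → contiguous
  patches whose class proportions match the request to within a cell.
- **Roads/rivers**: boundary-to-boundary polylines with random bends.
- **Population**: Gaussian foci plus a uniform floor, integerised by
  largest remainder so the total is conserved exactly.
- **Regions**: deterministic Voronoi partition around evenly spaced
  seed points (no randomness, by construction).
- **Facilities**: sampled without replacement with probability ∝
  population (plus a small floor), restricted to non-barrier cells.
- **Survey**: clusters allocated to regions by largest-remainder
  proportionality, placed at cell centres with finite travel time
  (placements on barriers/unreached cells are resampled and logged);
  households carry 0–3 children (Poisson(0.81) truncated at 3 — 0.81
  children per household matches the ~0.8 ratio typical of these
  surveys); child fever ~ Bernoulli(regional prevalence); attendance
  given fever ~ Bernoulli(Y(true travel time)). The true travel time is
  written into every record so recovery tests need no re-extraction.

What the generator does **not** emulate, hence what passing tests do not
establish about real data: survey design weights and two-stage sampling
variance, GPS displacement of cluster coordinates, facility choice
beyond the nearest-by-time rule, covariate-driven utilisation (income,
severity, provider quality), realistic road-network topology, seasonal
friction, and dasymetric population error. Results on real surveys
inherit all of those.

## Problem sizes and determinism

The shipped tests and the acceptance script run end-to-end scenarios at
60 × 60 km and shortest-path oracle checks at 12–15 cells a side with up
to 3 facilities — sizes chosen so the whole suite exercises every stage
in seconds while remaining large enough for the statistical checks
(50 replicates × 50,000 children for parameter recovery). All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical configuration and seed give
byte-identical output files.

## Known limitations

- Planar metre coordinates only; inputs must be pre-projected. No CRS
  machinery, no great-circle corrections.
- Isotropic slope effect (|tan θ|): no uphill/downhill asymmetry.
- One friction value per cell: a 1 km cell crossed by a road is "road"
  for every journey through it.
- The travel-time graph is the raster; vector network routing (one-way
  streets, junctions) is out of scope.
- Catchment thresholding is crisp: a cell at 181 minutes is outside.
- Fever burden assumes one episode per child per reporting period and
  region-constant prevalence.
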