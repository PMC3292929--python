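# careseek

Travel-time accessibility surfaces, logistic distance-decay utilisation
models, and under-five fever-burden estimation for public health
facilities.

## The problem

In most of sub-Saharan Africa, where a child with fever is treated — or
whether they are treated at all — depends heavily on how long it takes to
reach the nearest public health facility (PHF). National household surveys
(Malaria Indicator Surveys and their relatives) record treatment-seeking
for recent fever in children under five, and gridded population maps and
facility censuses exist for many countries. `careseek` combines these to:

1. build a **friction ("cost") surface** of per-pixel permissible travel
   speeds from land cover, roads, rivers and terrain, assuming mixed
   walking / cycling / motorised journeys;
2. accumulate **least-cost travel time** from every facility over the
   1 km grid (multi-source Dijkstra, 8-connected, with slope-corrected
   walking speeds), and allocate every pixel to its least-cost facility;
3. fit a **three-parameter logistic distance-decay model** of public
   facility attendance against travel time from the survey data;
4. delineate **facility catchments** under a travel-time threshold
   (default 3 hours), convert gridded population into expected under-five
   fever cases via regional prevalence, and estimate how many of those
   cases are **likely and unlikely to be treated in the public sector**.

It is aimed at epidemiologists and health-system planners who need
catchment populations for incidence denominators, commodity forecasting
or gap analysis, and at methodologists who want a fully synthetic,
reproducible sandbox for accessibility models.

## The model

Walking speed on slope θ follows Tobler's hiking function

    V(θ) = 6 · exp(−3.5 · |tan θ + 0.05|)   km/h

(about 5.0 km/h on flat ground, 3.71 at 5°, 1.41 at 20°). Per-cell base
speeds come from a standard land-cover/road table (walking 2–5 km/h by
cover class, cycling 10 km/h on tertiary roads, motorised 60–80 km/h on
secondary/primary roads; water and major rivers are barriers). The
probability that a febrile child attends a PHF at travel time *t* minutes
is

    Y(x) = C / (1 + e^((A − x)/B)),   x = log₁₀ max(t, 1)

where **C** is the limiting probability of attendance at zero travel time
(an upper asymptote that may be well below 1 — proximity alone never
guarantees attendance), **A** the inflection location on the log scale,
and **B** (< 0) the decay rate. The model is fitted by nonlinear least
squares to attendance proportions in 15 quantile bins of log travel time,
with multi-start initialisation and asymptotic t-statistics per
coefficient. Expected attendees per pixel are `fever cases × Y`, and
summaries aggregate by region, travel-time band, probability band or
catchment.

## Worked example

Run the full pipeline on a synthetic 60 km × 60 km scenario (9 regions,
12 facilities, a 120-cluster × 25-household survey):

```python
from careseek.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="out", seed=7, scenario={
    "grid": {"n_rows": 60, "n_cols": 60, "cell_size": 1000.0},
    "seed": 7, "n_regions": 9, "n_facilities": 12,
    "n_clusters": 120, "households_per_cluster": 25,
})
art = run_pipeline(cfg)
print(art.decay.summary())
```

```
Three-parameter logistic distance-decay model
==============================================================
Transform: log10(minutes), floor 1 min; bins: 15 (quantile)
Fever cases: 361   SSR: 0.06409   RSE: 0.07308   df_resid: 12
--------------------------------------------------------------
              coef     std err         t       P>|t|
     C      0.7178      0.0209     34.35    2.36e-13
     A      2.4641      0.0826     29.83    1.26e-12
     B     -0.0340      0.0524     -0.65       0.528
==============================================================
```

The fitted ceiling C ≈ 0.72 says that even next door to a facility about
28% of fever cases would not attend; the large standard error on B
reflects that a survey of 361 fevers concentrated near facilities barely
constrains the decay rate. The cumulative travel-time summary
(`art.summaries["time_bands"]`) then reads:

```
   stratum  children_u5  fever_cases  expected_attendees  pct_attendees
 <= 30 min       2088.0        320.0               229.0           72.0
 <= 60 min       6912.0       1141.0               819.0           72.0
<= 120 min      13082.0       2246.0              1612.0           72.0
<= 180 min      15050.0       2632.0              1889.0           72.0
 > 180 min       1450.0        284.0               121.0           43.0
     Total      16500.0       2916.0              2010.0           69.0
```

i.e. of 16,500 synthetic under-fives, 15,050 live within the 3-hour
catchment of some facility; of 2,916 expected fever cases, roughly 69%
would be treated in the public sector, dropping to 43% beyond 3 hours.

The same stages are available as a CLI
(`careseek simulate | friction | traveltime | extract | fit-decay |
predict | burden | run`), e.g.

```sh
careseek run --config config.json
```

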