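# habsuit

Presence-only habitat suitability modelling for gridded marine environmental
data. The package implements an end-to-end pipeline for biogenic-reef habitat
assessment:

* **spatial core** (`habsuit.grid`, `habsuit.io`) — regular lon/lat grid
  layers with nodata masks, ESRI ASCII grid and single-band GeoTIFF I/O,
  occurrence CSVs, region GeoJSON, spherical distances/areas
  (R = 6371 km) and Horn 3×3 percent slope.
* **synthetic data** (`habsuit.synth`) — smooth environmental fields with a
  latitudinal temperature gradient, a categorical landscape layer, a land
  mask and occurrence records clustered into separated populations drawn
  from a known "true" envelope, so every stage is testable offline.
* **environmental envelope analysis** (`habsuit.envelope`) — single-linkage
  population grouping (10 km default) under great-circle distance, 1 km bed
  buffers, interquartile (type-7) preferred ranges per variable,
  median-rule landscape preference, and envelope masking with area
  accounting.
* **maximum-entropy model** (`habsuit.maxent`) — from-scratch
  presence-background Gibbs model with linear/quadratic/categorical
  features scaled to [0,1], L1-regularized L-BFGS fitting, raw and
  entropy-calibrated logistic outputs, clamped scenario projection,
  global / 20 km-bias background sampling and jackknife variable
  contributions.
* **validation** (`habsuit.validation`) — repeated random hold-out splits,
  Mann–Whitney AUC against background, and the
  excellent/good/poor/random performance rating.
* **scenarios** (`habsuit.scenarios`) — linear uniform ocean warming
  (4.0 °C between 2009 and 2100 by default; increments 0.92/1.80/3.12/4.00 °C
  for 2030/2050/2080/2100) applied to the temperature layer only.
* **accounting** (`habsuit.accounting`) — ten probability bands, the
  most/less/unsuitable categories (MS = [0.5, 1.0], LS = [0.1, 0.5),
  US = [0.0, 0.1)), per-region area tables, integer percent-loss tables and
  envelope-vs-model overlap statistics.
* **pipeline** (`habsuit.pipeline`, `habsuit.cli`) — one-config orchestration
  with deterministic per-stage seeds and a reproducibility manifest.

## CLI

All functionality is exposed through the `habsuit` entry point:

```sh
habsuit simulate --seed 1 --out data/                 # synthetic stack + occurrences + regions
habsuit eea --stack data/stack --occurrences data/occurrences.csv --out eea/
habsuit maxent fit --stack data/stack --occurrences data/occurrences.csv \
    --mode global --out model.json
habsuit maxent predict --model model.json --stack data/stack --out suit.asc
habsuit validate --stack data/stack --occurrences data/occurrences.csv --out val/
habsuit scenario --stack data/stack --year 2050 --out warmed/
habsuit assess --suitability 2009 suit.asc --regions data/regions.geojson --out tables/
habsuit run-all --seed 1 --out run/                   # the whole pipeline
```

`run-all` executes every stage for both background modes (global and 20 km
bias), writes the envelope JSON, fitted models, validation tables,
per-epoch suitability rasters and the area/percent-loss tables, and records
a manifest whose output hashes are identical across re-runs with the same
configuration. The default synthetic domain is a 200×200 grid and the full
pipeline completes in a few seconds on one CPU.

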