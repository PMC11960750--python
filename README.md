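# herdmap

Map where — and how intensely — grazing livestock are active, from the
low-frequency telemetry that virtual-fencing collars record anyway: GPS
fixes (≈15 min apart when animals are active, 1–2 h when resting), a
30-min cumulative activity index, and 30-min collar temperatures.

Two utilization-distribution estimators are provided on a common 15 m
grid:

- **cell count** — fast dwell-time / activity / temperature accumulation
  per cell, with gap capping and time-window filters (hour of day,
  night/morning/afternoon/evening, 14-day blocks);
- **Brownian-bridge movement model (BBMM)** — bridge-integrated occupancy
  plus an activity-weighted extension that spreads each 30-min activity
  count along the estimated path as a time-integrated rate, conserving
  total activity. The Brownian motion variance is estimated per animal by
  leave-one-out maximum likelihood.

On top of the surfaces: core/full-range isopleths (50 % / 95 % of mass),
per-region range summaries, Bhattacharyya-coefficient similarity
matrices, and temporal analytics (activity-vs-observed-grazing
regression, intensity thresholding, bouts, diurnal and fortnight
profiles, collar-vs-weather-station temperature comparison). A seeded
synthetic herd generator produces collar-like data with per-minute ground
truth so the whole pipeline is testable offline.

## CLI

Every subcommand writes its outputs plus a `manifest.json` (resolved
parameters, input SHA-256 digests, seed, version) under `--out`.

```sh
# synthetic herd with ground truth (collar.csv, observations.csv, truth.csv)
herdmap simulate --seed 42 --out sim/

# utilization rasters (CSV + JSON sidecar)
herdmap map --collar sim/collar.csv --method cellcount --metric occupancy --out occ/
herdmap map --collar sim/collar.csv --method bbmm --metric cum-activity \
            --sigma2 auto --loc-error 5 --nodes 100 --out cum/

# windows: full | tod:night|morning|afternoon|evening | hour:<h> | fortnight:<k>
herdmap map --collar sim/collar.csv --window tod:morning --out morning/

# isopleths and similarity
herdmap ranges --raster occ/raster.csv --levels 0.5,0.95 --out ranges/
herdmap compare --inputs occ/raster.csv --inputs cum/raster.csv --out bc/

# temporal analytics
herdmap validate-grazing --collar sim/collar.csv --obs sim/observations.csv --out val/
herdmap profile --collar sim/collar.csv --group per-animal --out prof/
herdmap temperature --collar sim/collar.csv --station station.csv --out temp/
```

Input layout: a canonical collar CSV/TSV with columns
`animal_id, time, record_type (fix|activity|temperature), lat, lon,
activity_index, temp_c` (unused fields empty; other layouts adapt via a
JSON column mapping), and an observation CSV with
`animal_id, minute, label (grazing|non_grazing), observer_id`.

## Package layout

| module | role |
| --- | --- |
| `herdmap.ingest` | read/validate collar + observation files, local equirectangular projection |
| `herdmap.grid` | grid specification, cell location, rasters, raster CSV/JSON I/O, region masks |
| `herdmap.windows` | time-of-day / hourly / fortnight / custom temporal filters |
| `herdmap.cellcount` | cell-count occupancy, cumulative/average activity, mean temperature |
| `herdmap.bbmm` | Brownian-bridge occupancy, activity-weighted extension, variance estimation |
| `herdmap.similarity` | volume isopleths, range summaries, Bhattacharyya comparisons |
| `herdmap.temporal` | grazing validation regression, thresholds, bouts, profiles, temperature series |
| `herdmap.simulate` | seeded synthetic herd + Brownian tracks with ground truth |
| `herdmap.cli` | `herdmap` entry point and run manifests |
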