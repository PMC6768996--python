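# dfadrift

Analysis of drifting Fish Aggregating Device (dFAD) beaching from
satellite-buoy tracks and Lagrangian particle simulations.

Tropical purse-seine fleets deploy tens of thousands of dFADs — rafts with
a ~50 m submerged appendage and a satellite buoy — and many eventually
strand on coral reefs and shorelines. `dfadrift` implements, as a tested
and reusable pipeline, the analysis chain needed to quantify where and why
that happens: cleaning and segmenting raw buoy transmission tables,
rule-based beaching detection, deployment-hotspot and density estimation,
residual-based classification of notable beaching cells, Lagrangian
simulation of virtual dFADs under contrasting deployment scenarios, and
source–sink connectivity by drift time. A synthetic-world generator
(velocity fields, island land masks, ground-truthed fleets) gives every
stage a testable input with no external data. It is aimed at fisheries
oceanographers and movement ecologists working with drifter-like
telemetry.

## The method in brief

- **Cleaning.** Transmissions are filtered (duplicates, single-position
  and short tracks, implied speeds > 30 km/h), then each position is
  classified *at-sea* vs *on-board* by a random forest over
  {Δt, speed, acceleration, heading change, distance to port}, smoothed by
  removing isolated label runs (< 3), and split into drift segments whose
  first position is the deployment.
- **Beaching rule.** A segment beaches iff its last position is ≤ 10 km
  from shore, > 10 km from every major port, and its last 3 transmissions
  are co-located within 1 km. Events aggregate onto 1° coastal cells.
- **Densities.** Standardized dFAD density per 1° cell counts distinct
  (buoy, ISO week) pairs; deployments get a 2D Gaussian product-kernel
  density (normal-reference bandwidths, the `kde2d` convention), and
  hotspots are cells above the 95th percentile of all cell values.
- **Notable cells.** Per-(cell, quarter) beaching counts are regressed on
  local density with a seasonal factor (OLS, n ~ density + C(quarter));
  residuals above the 90th percentile mark *beaching-prone* cells, below
  the 10th with high density *beaching-resilient*, central residuals with
  counts above the 80th percentile *high-density* cells.
- **Simulation.** Virtual dFADs are advected through gridded u, v fields
  (depth-averaged over the top 50 m) by RK4 with bilinear/linear
  interpolation, weekly cohorts, 365-day lifetime, 6-month spin-up, under
  *uniform* (5 particles per 1° sea cell, > 11,000 per cohort on the
  130°E–140°W, 15°S–10°N study domain) or *observed-deployment* (draws
  from the deployment KDE) seeding.
- **Connectivity.** Every entry of a particle (or beached dFAD) into a
  beaching cell yields a beaching trajectory; matrices report the
  percentage of trajectories per (beaching region × source region ×
  drift-time bin <1, 1–3, 3–6, 6–9, >9 months), alongside per-bin spatial
  probability maps of pre-beaching positions.

## Worked example

```python
import numpy as np, pandas as pd
from dfadrift import GridSpec
from dfadrift.synth import SyntheticWorldConfig, FleetConfig, make_land_mask, \
    gen_velocity_field, gen_fleet_tracks
from dfadrift.cleaning import compute_features, train_position_classifier, \
    clean_and_segment
from dfadrift.beaching import detect_all, aggregate_beaching_cells

grid = GridSpec(150, 170, -8, 0, 1.0)
world = SyntheticWorldConfig(
    grid=grid, islands=[(153.0, -4.0, 60.0), (163.0, -2.0, 45.0)],
    jet_speed=0.3, eddy_count=4, eddy_amplitude=0.1,
    time_span_days=60.0, ports=[(150.5, -7.5)], rng_seed=0)
mask = make_land_mask(world)
field = gen_velocity_field(world, mask)

fleet = FleetConfig(n_buoys=80, rng_seed=1)
tracks, truth, events = gen_fleet_tracks(fleet, field, mask, grid)

# train the at-sea/on-board classifier on an independent fleet
train_tracks, train_truth, _ = gen_fleet_tracks(
    FleetConfig(n_buoys=80, rng_seed=2), field, mask, grid)
feats = [compute_features(g, mask=mask)
         for _, g in train_truth.groupby("buoy_id") if len(g) >= 3]
labels = [g["label"].to_numpy()
          for _, g in train_truth.groupby("buoy_id") if len(g) >= 3]
model = train_position_classifier(pd.concat(feats), np.concatenate(labels),
                                  rng_seed=0)

result = clean_and_segment(tracks, model, mask=mask)
events_det, _ = detect_all(result.segments, mask, grid)
cells = aggregate_beaching_cells(events_det, grid)

print(f"transmissions: {len(tracks)}, drift segments: {len(result.segments)}")
print(f"classifier held-out accuracy: {model.holdout_accuracy:.3f}")
print(f"beaching events: {len(events_det)} in {len(cells.cells)} cells")
print(f"ground-truth beachings: {(events.event == 'beaching').sum()}")
```

Output:

```
transmissions: 55555, drift segments: 124
classifier held-out accuracy: 0.999
beaching events: 6 in 3 cells
ground-truth beachings: 6
```

The 80-buoy fleet pinged 55,555 times over 60 days and split into 124
drift segments after on-board phases were removed; the beaching rule
recovered all 6 ground-truth strandings on the two islands, falling in 3
distinct 1° coastal cells.

## Command line

The same stages run behind a subcommand CLI with a YAML config
(`dfadrift run-all --demo --out runs/demo` runs a small self-contained
synthetic world end-to-end; stages are resumable and individually
invocable: `synth`, `clean`, `detect`, `density`, `classify`, `simulate`,
`connect`).

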