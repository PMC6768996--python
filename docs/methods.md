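# Methods

`dfadrift` analyses stranding ("beaching") of drifting Fish Aggregating
Devices (dFADs) — satellite-tracked rafts deployed by tropical purse-seine
fleets — from buoy transmission tables and Lagrangian particle simulations.
This note documents the models, rules, parameters and numerical choices,
and what the synthetic-data tests do and do not demonstrate.

## Trajectory cleaning and segmentation

Raw transmissions (buoy id, timestamp, lon, lat) are cleaned in four steps.

1. **Basic filters.** Exact duplicate timestamps are dropped; positions
   whose implied speed from the previous kept fix exceeds `max_speed_kmh`
   (default 30 km/h — well above passive drift, below sustained vessel
   transit) are dropped by a greedy scan; single-position tracks and tracks
   active for less than `min_duration_h` (default 24 h) are removed. Every
   rejection carries a reason code.
2. **Features.** Per position: time gap, speed (haversine/Δt on a 6371 km
   sphere), acceleration, heading change (initial great-circle bearings,
   folded to [0, 180]°), and distance to the nearest major port (capped at
   20,000 km when no ports are configured). Undefined derivatives on the
   first/second rows are filled with 0.
3. **At-sea / on-board classification.** A random forest
   (scikit-learn, 100 trees, fixed seed) trained on ground-truthed
   synthetic fleets; the on-board probability ≥ 0.5 decides the label. A
   speed-plus-port threshold rule is provided as a fallback. Vessel motion
   (~20 km/h) and drift (≲3 km/h) are well separated in the synthetic
   worlds, so held-out accuracy is near 1; real telemetry with mixed
   transmission modes will be harder, and nothing here validates the
   classifier beyond the separability the generator creates.
4. **Desegmentation and splitting.** Label runs shorter than `min_run`
   (default 3) are iteratively flipped to their neighbours' label,
   shortest-first, interior runs before edge runs, until no short run
   remains — an idempotent smoothing that never increases the number of
   runs. Maximal at-sea runs become drift segments; the first position of
   a segment is its deployment.

Conservation holds by construction: every input position is rejected with
a reason, labelled on-board, or belongs to exactly one drift segment.

## Beaching rule

A drift segment ends in a beaching event iff (i) its final position is
within 10 km of shore, (ii) it is more than 10 km from every major port,
and (iii) its last 3 transmissions are pairwise within `same_loc_tol_km`
(default 1 km — below hourly drift displacement, above GPS jitter).
Distance to shore is evaluated against a rasterized land mask: great-circle
distance to the nearest land-cell centre minus half a cell diagonal,
floored at 0 (a raster stand-in for a vector coastline; at the default
0.05° mask resolution the bias is under ~4 km and the 10 km rule is
stable). Events are tagged with the 1° grid cell of the final position and
the calendar quarter/year. Latitude 0 and the 175°E meridian belong to the
southern and eastern regions respectively (strict ">0°N", ">=175°E").

## Densities and hotspots

**Standardized dFAD density** per 1° cell counts distinct (buoy, ISO week)
pairs with at least one at-sea transmission in the cell, so one buoy can
count in several weeks and cells but hourly pinging within a week counts
once. **Deployment density** is a 2D Gaussian product-kernel estimate on a
0.1° lattice with per-axis normal-reference bandwidths
(1.06·min(sd, IQR/1.34)·n^(−1/5), the `kde2d` convention), normalized to
integrate to 1 over the domain. **Hotspots** are 1° cells whose mean
density strictly exceeds the 95th percentile (linear interpolation) of all
cell values; 4-connected components are labelled 1..k by decreasing mass.
By construction the strict-percentile rule selects between 0 and ~5% of
cells (0 for an exactly flat surface).

## Notable beaching cells

Counts per (cell, quarter) record are regressed on local density with
quarter as an additive categorical factor (statsmodels OLS); with a single
quarter the factor is dropped with a warning. Residual percentiles then
classify records: beaching-prone above the 90th percentile;
beaching-resilient below the 10th *and* density above the median
(operationalizing "high local density"); high-density when the residual
lies in the central 45–55% band and the count exceeds the 80th percentile
of counts. The central band defaults to residuals; a density-based reading
is available behind `center_band_on="density"`. Percentiles use the
linear-interpolation definition with strict inequalities at the extremes.

## Lagrangian simulation

Particles are advected offline through gridded (time, lat, lon) velocity
fields in m/s, depth-averaged over the top 50 m when a depth axis is
present (the median drogue depth of a dFAD appendage). Integration is RK4
with dt = 1 h by default, bilinear interpolation in space and linear in
time; positions are recorded daily. A particle stepping into a land cell
halts at its last sea position (beached objects are not re-suspended); a
particle leaving the domain is frozen and flagged; lifetime is capped at
365 days. Entering a beaching cell does **not** terminate a particle —
the analysis is about cell entry, not physical grounding.

Verification: in uniform flow the 10-day displacement matches
0.3 m/s·10 d = 259.2 km to ~1e-10 km; a solid-body rotation orbit closes
within 3e-6 km at dt = 1 h; and halving dt shrinks the closed-orbit error
by 16.0× (4th order). The order check samples the rotation field
analytically, because bilinear interpolation of a gridded field leaves a
dt-independent error floor of a few metres per orbit that would mask the
ratio.

Two seeding scenarios: **uniform** places exactly `mean_density` (default
5) particles uniformly in the sea area of every 1° sea cell — 11,250 per
cohort on the 90×25-cell study domain; **weighted** draws the same cohort
size i.i.d. from the deployment kernel density restricted to sea
(multinomial over lattice nodes + in-node jitter + land rejection), so the
two experiments are mass-comparable. Cohorts are released every 7 days;
releases during the spin-up window (default 183 days, the average dFAD
lifetime) are advected but excluded from analysis.

**Beaching trajectories**: for each analysis-period particle and each
beaching cell it enters, the first entry (at the daily recording cadence)
yields one independent trajectory truncated at entry. **Coastal
comparison**: mean daily particle count per cell versus observed
dFAD-weeks, Pearson-correlated over coastal cells (sea-containing 1° cells
within one cell, 8-neighbourhood, of a land-containing cell).

## Connectivity

Each beaching trajectory contributes its source position (deployment for
observed dFADs, release for particles) and its total drift time. Drift
times fall in bins <1, 1–3, 3–6, 6–9, >9 months with a 30.44-day month
(calendar months would make bins release-date-dependent). Sources are
labelled by deployment hotspot when they fall in a hotspot cell, otherwise
by geographic region (north of the equator, else longitude bands; the
study default splits at 175°E, synthetic worlds may use more bands);
sources outside the domain go to an explicit "external" column.
Percentages are normalized within each (beaching region, lag bin), so
populated rows sum to 100 exactly. Lag-density maps histogram positions at
each lag window before entry, normalized per bin; position-at-lag is
linearly interpolated between daily fixes (exact for linear motion), with
longitudes unwrapped across the antimeridian.

## Synthetic worlds

The generator emulates the western-central equatorial Pacific setting: a
westward jet (default 0.3 m/s, the prevailing equatorial circulation)
plus Gaussian stream-function eddies (default ~150 km radius, ~0.15 m/s)
whose centres drift westward with the jet; circular islands rasterized on
a 0.05° mask; velocities zeroed on land. Fleets ping hourly; buoys may
start with an on-board transit at 5.5 m/s (~20 km/h, vessel speed) toward
a deployment point drawn uniformly over sea or from a hotspot mixture;
drift integrates the same RK4 kernel as the simulator plus isotropic
process noise (σ = 0.5 km per step) while moving; per-day recovery and
deactivation hazards; stranding when the drift step lands on a land cell,
after which the buoy re-transmits its resting position (a handful of
stationary pings, continuing past the end of the drift window as a real
beached buoy would) and then falls silent. Ground truth (per-ping labels,
deployments, beachings, recoveries) is emitted alongside, never inferred.

What the synthetic worlds do *not* contain: tidal and submesoscale
variability, transmission-mode changes, EEZ-boundary track truncation
(noted in the cleaning module as a known bias of real data), multi-dFAD
buoy reuse semantics beyond recovery/redeploy, and realistic vessel
logistics. Passing tests therefore demonstrate correctness of the rules
and numerics under controlled conditions, not performance on proprietary
fleet data.

The planted-outlier tables for the residual classifier place
anomalies of exactly ±5σ (replacing the noise term) on high-density
records; a draw-plus-offset construction would leave the planted and
nominal residual tails overlapping at n = 200 and make exact recovery a
coin flip, which is a property of the construction rather than of the
classifier.

## Problem sizes and reproducibility

The verification battery runs: beaching fidelity with 200 drift-only buoys
over 60 days (~35–50 ground-truth strandings); cleaning with two
independent 120-buoy fleets over 45 days; connectivity with ~39,000
particles over 200 days at dt = 2 h in a pure-jet world; the scenario
contrast with two ~21,000-particle experiments over 150 days at dt = 3 h.
These sizes were fixed once as desk-scale analogues of the study design.
All randomness flows through explicit integer seeds (numpy Generator);
fixed seed, step and field give bit-identical trajectories. netCDF-style
I/O uses the netCDF3 classic format via xarray's scipy engine.

## Known limitations

- Raster distance-to-shore underestimates near complex coastlines; the
  half-diagonal correction is exact only for a point directly off a cell
  corner.
- Beaching-cell entry times are resolved at the daily recording cadence,
  so drift times carry up to ±1 day discretization.
- Halted (stranded) particles stop contributing to density records after
  halting; pile-up of dead particles on coastal cells is deliberately not
  counted.
- The OLS count model ignores spatial autocorrelation and the
  count-valued nature of beachings (a Poisson/NB alternative is out of
  scope as a diagnostic only).
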