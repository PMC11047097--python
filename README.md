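# corrugo

Agent-based simulation and population-genetic analysis of bacterial biofilms
growing in open-top microwells whose bottom surface carries a sinusoidal
corrugation, together with the statistics used to characterise clonal
dynamics on such substrates:

* **`corrugo.well_geometry`** — well domain, corrugated-bottom profile
  `h(x) = (A/2)(1 - cos(2πx/T))`, wall distance/normal queries, pocket
  indexing, and the pocket-count line `N = (T + width)/T`.
* **`corrugo.biofilm_sim`** — 2D spherocylinder agents with Hertzian-like
  cell–cell repulsion (`F = k o^{3/2}`), linear wall repulsion, breakable
  cell–wall adhesion springs, overdamped (Stokes-friction) dynamics,
  exponential elongation with symmetric division, heritable genotypes, and
  removal of cells through the open top.
* **`corrugo.clonal_stats`** — clone census and fractions, near-bottom
  transects, sector-boundary densities, mean sector size, the two-strain
  mixing statistic `H = f1 f2/(f1 + f2)`, founder-survival densities.
* **`corrugo.velocity_analysis`** — gridded velocity fields from snapshot
  pairs, continuity-equation growth rate `g = ∇·v`, bottom-distance
  stratified profiles of vertical velocity and horizontal-velocity fraction.
* **`corrugo.selection_fitness`** — time-varying fitness protocols (e.g.
  stepwise antibiotic exposure), strain-fraction series, logistic-replicator
  prediction and relative-fitness estimation, selection-suppression sweeps.
* **`corrugo.fixtures_io`** — YAML run configuration with strict validation,
  CSV persistence (snapshots, genealogy, fields, series), synthetic fixture
  generators, and the command-line interface.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria; the simulation
ensembles it uses are session-scoped fixtures, so the full suite performs
~30 desk-scale simulation runs and takes on the order of 15–25 minutes on
one CPU.

## Command line

```sh
corrugo simulate --config run.yaml --out out/ --seed 1 --t-end 72 --snapshot-every 2
corrugo stats    --snapshots out/ --transect-offset 2 --out stats.json
corrugo velocity --snapshots out/ --spacing 2 --out field.csv
corrugo select   --wells flat,10x5 --seeds 5 --out results/
corrugo fixtures --kind sector --n-sectors 11 --out sectors.csv
```

A default desk-scale configuration ships with the package
(`corrugo.fixtures_io.default_config_path()`).

## Units and conventions

Lengths in µm, time in hours, forces in pN.  The origin sits at the
bottom-left groove level with y increasing toward the open top; grooves of
the corrugation are located at `x = kT`, so side walls abut half-grooves
whenever `T` divides the width.  The desk parameter profile uses stiffness,
friction and growth values rescaled for workstation-scale wells while
preserving the 10:1 wall:adhesion stiffness ratio and the quasi-static
(overdamped) regime; `reference_profile()` keeps the reference stiffness
constants (wall 1e7, adhesion 1e6 pN/µm) with a correspondingly small time
step.
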