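# timbersim

A spatially explicit, annual-timestep simulator of a tropical timber
industry on a raster landscape. The model combines:

- **cost-distance economics** — per-cell friction surfaces (land cover,
  road/waterway class, protection zoning with prohibitive barrier values),
  least-cost accumulated transport cost to the cheapest logging center, and
  per-cell net rent `v × area × (price − (HC + TC) × (1 + r))`;
- **two harvest modes** — reduced-impact logging (RIL: management units
  subdivided into annual production units, a per-hectare removal cap of
  `0.86 m³/ha/yr × cycle length`, single entry per cycle) and conventional
  logging (CL: unrestricted removal, re-entry allowed);
- **logging-center dynamics** — demand-limited capacity growth (≤ 20 %/yr),
  decline tracking the profitable volume in each center's area of
  influence, shutdown, and seeded emergence of new centers 200–500 km away;
- **road expansion** — unpaved roads built each year along least-cost paths
  from newly harvested cells to the existing network, progressively
  cheapening access;
- **scenario comparison** — built-in `LEGAL` (RIL everywhere harvest is
  allowed) and `ILLEGAL` (CL on private and undesignated lands) scenarios,
  per-category ledgers, summary tables and leakage statistics;
- **synthetic landscapes** — a seeded generator of autocorrelated volume
  fields, contiguous zoning mosaics, road skeletons and center tables, so
  the whole pipeline is testable without any external data.

## CLI

```sh
# generate a synthetic landscape (or a pinned fixture) as plain-text rasters
timbersim synth --spec spec.yaml --seed 1 --out landscape/
timbersim synth --fixture leakage_demo --out landscape/

# inspect friction / accumulated cost / areas of influence
timbersim costmap --landscape landscape/ --out cost/

# run one scenario for a 30-year cycle
timbersim simulate --landscape landscape/ --scenario LEGAL --seed 1 --out legal/
timbersim simulate --landscape landscape/ --scenario ILLEGAL --seed 1 --out illegal/

# per-category summary tables and scenario-comparison percentages
timbersim report --legal legal/ledger.csv --illegal illegal/ledger.csv --out report/cmp
```

Scenarios can also be custom YAML files mapping zoning categories to
harvest modes (`category_mode: {undesignated_federal: none, ...}`).

## Library sketch

```python
import timbersim as ts

grid, centers = ts.generate_landscape(ts.LandscapeSpec(n_rows=100, n_cols=100, seed=3))
legal, illegal = ts.run_pair(grid, centers, ts.SimulationParams(rng_seed=3))
table_l = ts.summarize(legal, exchange_rate=1.995)
table_i = ts.summarize(illegal, exchange_rate=1.995)
cmp_ = ts.compare_scenarios(table_l, table_i)
print(cmp_.pct("total", "volume_mm3"))
```

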