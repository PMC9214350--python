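# icerank

Value-for-money league tables for early childhood development (ECD)
interventions: standardized per-child costing, aggregation of domain-level
effect sizes (Cohen's *d*) under configurable weight schemes, incremental
cost-effectiveness ratios (ICERs) with propagated 95% uncertainty ranges,
and ranked league tables.

The package ships a curated portfolio of 16 intervention arms from 15
published early-parenting / psychosocial-stimulation studies (effects,
uncertainty ranges, local and LMIC-standardized per-child costs) and
reproduces the published league tables cell-for-cell: 48 ICERs, 96
uncertainty bounds, 48 ranks, and all effect cells.

## Library overview

- `icerank.core_model` — domain types (`InterventionArm`, `EffectEstimate`,
  `CostRecord`, ...), `validate_portfolio` (findings, not exceptions), and
  CSV/JSON portfolio serialization.
- `icerank.costing` — ingredients-based unit costs, CPI inflation to a
  reference year, and wage re-referencing of workforce ingredients
  (`standardize_unit_cost`). CPI/wage tables are YAML configuration.
- `icerank.effects` — `make_scheme("averaged" | "summed", effects)` and
  `aggregate`, with bound-wise uncertainty propagation at full precision.
- `icerank.cea` — `icer_point`, `icer_interval`, `evaluate_arm`,
  `rank_arms`, display rounding, and an optional seeded
  `monte_carlo_interval` extension (normal resampling of effects).
- `icerank.datasets` — `load_paper_dataset()` (checksummed bundled
  portfolio) and `generate_portfolio` (seeded synthetic portfolios with
  analytically implied ground-truth ICERs).
- `icerank.golden` — cell-level diff of computed league tables against the
  published values.

```python
from icerank import evaluate_arm, load_paper_dataset, rank_arms

arms = [a for a in load_paper_dataset() if a.league_eligible]
table = rank_arms([evaluate_arm(a, "averaged", "standardized") for a in arms])
print(table.to_frame())
```

A note on display rounding: money is shown in whole dollars and effects to
two decimals, using half-to-even on decimal-snapped values. Ratios of the
printed two-decimal effects and whole-dollar costs land exactly on .5
boundaries, and half-to-even is the only convention consistent with every
published cell. All ranking and interval arithmetic uses unrounded values.

## Command line

```bash
icerank rank --input paper-fixture --scheme averaged --basis standardized
icerank rank --input my_portfolio.csv --scheme summed --basis local --format csv
icerank standardize --ingredients ingredients.csv --params params.yaml
icerank reproduce-paper          # exits 0 iff every published cell matches
icerank simulate --n-arms 10 --seed 42 --output synthetic.csv
icerank export-fixture --output portfolio.csv
```

Exit codes: 0 success, 1 golden mismatch (`reproduce-paper`), 2 usage or
validation error. Logs go to stderr, data to stdout or `--output`.

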