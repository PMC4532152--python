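# copdcost

Register-based, top-down cost-of-illness accounting for COPD and a
smoking-standardised projection model for future annual costs.

The package has four parts:

- **`copdcost.synth`** — seeded synthetic register extracts (hospital days,
  outpatient visits, drug purchases with reimbursement flags, sickness
  allowance spells, disability pensions) plus aggregate series (price index,
  smoking prevalence, population counts). Event counts per age–sex stratum
  and year are Poisson with mean `rate × weighted smoker equivalents`, so
  every downstream stage is testable without any external data.
- **`copdcost.accounting`** — the historical accounting: filter care events
  by primary ICD-10 rubric (prefix J43/J44), filter drug purchases by
  special-reimbursement entitlement combined with anticholinergic use, price
  utilisation with inflation-adjusted unit costs, convert allowance days and
  pension person-years into lost man-years, and assemble per-year integer-Euro
  cost breakdowns plus per-100,000 normalisations.
- **`copdcost.projection`** — base-year stratum costs divided by weighted
  smoker-equivalent counts (weights 1 / 1 / 0.75 / 0.5 for active smokers and
  1–3y / 3–5y / 5–10y quitters), linear extrapolation of smoking-category
  fractions, multiplication with a population projection and a flat annual
  inflation factor. Indirect costs accrue only below the retirement age.
- **`copdcost.pipeline` / `copdcost.cli`** — schema-validated tab-separated
  IO, a reproducible simulate → cost → project pipeline, and a CLI.

Published Finnish national reference tables for 1996/2006 (unit costs,
register utilisation counts and the cost breakdown) ship as plain-text
fixtures under `copdcost/data/` and are used by the tests and the acceptance
report.

## CLI

```sh
copdcost simulate --config config.yaml --seed 1 --out out/
copdcost cost --registers out/registers --price-index out/price_index.tsv \
    --population out/population.tsv --out out/cost
copdcost project --standardised out/cost/standardised_costs.tsv \
    --smoking out/smoking.tsv --population out/population.tsv \
    --base-year 2006 --years 2007:2030 --inflation 0.02 \
    --retirement-age 65 --weights 1,1,0.75,0.5 --out out/proj
copdcost report --config config.yaml --seed 1 --out out/report
```

`report` runs the whole pipeline from one YAML config (see
`copdcost.pipeline.PipelineConfig`); identical config + seed gives
byte-identical output files.

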