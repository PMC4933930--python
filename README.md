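# niptcca

Cost-consequence evaluation of adding non-invasive prenatal testing (NIPT)
as a contingent test to a national Down's syndrome screening programme.

The package implements:

- **`niptcca.params`** — the screening-pathway parameterisation
  (`ScreeningParams`, with `rapid` and `national` presets), the seven
  testing strategies (`Strategy`, `enumerate_strategies`), and a flat
  YAML parameter-file reader/writer that accepts percent or proportion
  units.
- **`niptcca.model`** — deterministic decision-tree evaluation of any
  strategy at national scale (`evaluate_pathway`) and incremental
  comparison against the current pathway (`incremental`), with
  expected-value (cohort-mean) arithmetic.
- **`niptcca.psa`** — probabilistic sensitivity analysis (`run_psa`):
  beta distributions for proportions built from effective study
  denominators, gamma (CV 20%) for the uncertain unit costs, Dirichlet
  coupling of the complementary high-risk testing choices, and
  equal-tailed 95% percentile intervals.
- **`niptcca.scenarios`** — one-way threshold analysis
  (`one_way_threshold`), cost-neutral NIPT price solving
  (`solve_cost_neutral_price`), price sweeps (`price_sweep`) and uptake
  scenario tables (`uptake_scenarios`).
- **`niptcca.cohort`** — synthetic individual-level cohorts with the full
  pathway flow (`simulate_cohort`), parameter re-estimation with exact
  Clopper-Pearson intervals (`estimate_params`), and diagnostic accuracy
  summaries (`diagnostic_accuracy`).
- **`niptcca.report` / `niptcca.cli`** — table writers using the
  publication conventions (money in GBP thousands, half-away-from-zero
  rounding) and a `click` command-line interface.

## CLI

```bash
niptcca table3 --preset national                  # 7-row pathway table (CSV)
niptcca table4 --preset national                  # deterministic incrementals
niptcca psa --preset national --n-sims 1000 --seed 42 --out table4.csv
niptcca threshold --preset national --strategy 150            # price
niptcca threshold --preset national --strategy 150 \
    --vary u_nipt_high --coupling complement_within_further_testing
niptcca price-sweep --preset national --min 50 --max 500 --step 10 --out fig4.csv
niptcca scenarios --preset national               # uptake scenario table
niptcca simulate --preset rapid --n 40527 --seed 1 --out cohort.csv
niptcca estimate --cohort cohort.csv --out params.yaml
```

Strategies are named `current`, `150`, `500`, `1000` and the
`*-nodirect` variants. `--params FILE` takes a flat YAML file (fields of
`ScreeningParams`, optional `preset:` fallback and `units: percent`).
All money values are 2012/13 GBP; rounded tables can be swapped for raw
values with `--raw`.

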