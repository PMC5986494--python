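# Input table formats

All five inputs are plain CSV with headers. `fopl-cea simulate-data`
writes conforming examples; `fopl_cea.pipeline.validate_inputs` checks
every rule below and reports all violations with row references.

Age groups are `[age_lo, age_hi)` in whole years and must partition
[0, 100) for each sex wherever they appear. `sex` is `female` or
`male`.

## products.csv
| column | type | rule |
|---|---|---|
| product_id | int | unique |
| category | str | food category name |
| ed_y0, ed_y1 | float | energy density kJ/100 g, pre/post; > 0 |
| labelled | bool | displayed the label post-implementation |

## consumption.csv
| column | type | rule |
|---|---|---|
| age_lo, age_hi | int | age group |
| sex | str | |
| category | str | |
| grams_per_day | float | ≥ 0 |

## population.csv
| column | type | rule |
|---|---|---|
| age_lo, age_hi, sex | | one row per stratum |
| size | float | cohort persons, ≥ 0 |
| bmi_mu, bmi_sigma | float | lognormal BMI, log scale; sigma > 0 |
| height_m | float | mean height, in [0.5, 2.1] |
| mortality | float | annual all-cause rate, in (0, 1] |
| yld | float | total years-lived-with-disability rate, in [0, 1) |

## diseases.csv
One row per disease × age group × sex.
| column | type | rule |
|---|---|---|
| disease | str | |
| age_lo, age_hi, sex | | |
| incidence, case_fatality, remission | float | annual rates in [0, 1) |
| disability_weight | float | in [0, 1); constant per disease |
| rr_per_5bmi | float | ≥ 0; constant per disease |
| rr_log_se | float | log-scale SE for the PSA |
| cost_per_case_year | float | 2010 A$ > 0; constant per disease |
| min_age | int | onset age (incidence 0 below) |

## costs.csv
| column | type | rule |
|---|---|---|
| item | str | e.g. industry, government, legislation |
| scenario | str | voluntary or mandatory |
| value, min, max | float | 2010 A$; min ≤ value ≤ max |
| schedule | str | one_off, per_cycle or annual |
| distribution | str | pert or gamma (PSA family) |

## YAML configs

`fopl-cea simulate-data --config` takes `SyntheticConfig` fields
(`seed`, `n_products`, `n_categories`, `uptake_target`,
`labelled_reform_mean`, `age_groups`, `n_diseases`, ...);
`fopl-cea run --config` takes `RunConfig` fields (`scenario`,
`attributable_fraction`, `discount_rate`, `wtp`, `horizon_age`,
`labelling_cycle_years`, `ref_bmi`, `n_iter`, `seed`, nested
`energy_weight` and `psa` blocks). CLI options override config values.
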