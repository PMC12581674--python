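# Input table schemas

## patients.csv — one row per enrolled patient

| column | type | notes |
| --- | --- | --- |
| id | string | unique patient identifier |
| arm | string | `calcifediol`, `calcitriol`, or `placebo` |
| age | float | years |
| sex | string | `F` / `M` |
| icu_type | string | `medical` / `surgical` |
| apache2 | int | APACHE II points |
| septic_shock | 0/1 | sepsis with vasopressors at enrollment |
| aki_on_enrollment | 0/1 | randomization stratum |
| weight | float | kg, > 0 |
| baseline_scr | float | mg/dL, > 0 |
| death_day | int or empty | day index (0-based) within 28-day follow-up |
| krt_start_day | int or empty | day index of KRT start |
| icu_days | int | ICU length of stay, days |
| hospital_days | int | hospital length of stay, days |
| egfr | float or empty | mL/min/1.73 m², input field |
| risk_factors | string | `;`-separated AKI risk-factor names |

## labs.csv — long format, one row per observation

| column | type | notes |
| --- | --- | --- |
| patient_id | string | must exist in patients.csv |
| analyte | string | `scr`, `25d`, `125d`, `calcium`, `phosphate`, `uop` |
| time_h | float | hours from enrollment, ≥ 0; strictly increasing per patient-analyte |
| value | float | > 0 |
| unit | string | `mg/dL`, `ng/mL`, `pg/mL`, `mL/kg/h` (or `mL/h` for urine output, converted by weight) |

Validation (`akirank.io.read_cohort`) reports every violation with its row
number and refuses partially valid inputs.

## Outputs

- `stages.csv`: `patient_id, time_h, stage, trigger`
- `ranks.csv`: `patient_id, tier, rank, flag_imputed_zero`
- `subgroups.csv`: `subgroup, level, contrast, n_active, n_placebo, p_value, statistic, method`
- `outcomes.csv`: endpoint rows with per-arm summaries and contrast p-values
- `results.json`: arm sizes and primary rank-sum comparisons
- `manifest.json`: config hash, seed, package version, sha256 per output
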