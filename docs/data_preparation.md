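# Preparing a survey extract

The package consumes a flat person-day table; it does not parse raw
time-use survey deliverables (activity, roster, or "who" files) or build
survey weights. To analyse a real extract — e.g. the American Time Use
Survey 2003-2022 public-use files — flatten it to the canonical CSV schema
with one row per diary day:

| column         | content                                                    |
|----------------|------------------------------------------------------------|
| `age`          | respondent age in completed years at the diary day         |
| `year`         | diary calendar year                                        |
| `cohort_year`  | optional; birth year. Must equal `year - age`; derived if absent |
| `gender`       | `female` or `male`                                         |
| `minutes_alone`| outcome minutes for the diary day, in [0, 1440]. For the time-spent-alone analysis: sum of episode durations with no one else present, excluding work-related activities (and sleep/personal care, for which companionship is not collected) |
| `weight`       | positive diary-day survey weight (e.g. TUFNWGTP)           |
| `day_of_week`  | `Mon` .. `Sun` (full names accepted, case-insensitive)     |
| `holiday`      | boolean; diary day is a holiday                            |

Practical notes:

- Use the *diary-day* weight, not the interview weight; the fitted model
  weights every observation by this column and builds its contrast bases
  from per-group weight sums.
- Restrict to the analysis window with `FilterSpec` (defaults: ages 15-79,
  years 2003-2022) rather than pre-filtering, so the run manifest records
  the row counts before and after filtering.
- Rows with missing outcome or weight are rejected at validation and
  listed in the validation report (listwise deletion); nothing is imputed.
- Tab-separated extracts load with `read_microdata(path, delimiter="\t")`.

`apcbounds fit --data extract.csv --out results/` then runs the full
stratified analysis.
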