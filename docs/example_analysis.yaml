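# Example configuration for `scalemok run --config docs/example_analysis.yaml`.
# Generate a matching dataset first:
#   scalemok simulate --seed 7 --n 3000 --out sim/
input:
  data: sim/responses.csv
  items:
    [anxiety, sad, fatigue, loneliness, concentrating_thinking, no_control,
     pain, daily_activities, mobility]
  level_range: [1, 5]
  group_columns: [country, gender, age_band, long_term_condition, carer]

scales:
  full:
    [anxiety, sad, fatigue, loneliness, concentrating_thinking, no_control,
     pain, daily_activities, mobility]
  psychosocial:
    [anxiety, sad, fatigue, loneliness, concentrating_thinking, no_control]
  physical: [pain, daily_activities, mobility]

bounds: [0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6]
minvi: 0.03
minsize: null          # null -> N/10 ladder
bootstrap_reps: 1000
aisp_bootstrap_reps: 200
alpha: 0.05
strata: [country, gender, age_band, long_term_condition, carer]
known_groups: [long_term_condition, carer]
stratum_floor: 500
seed: 0
outdir: scalemok_out
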