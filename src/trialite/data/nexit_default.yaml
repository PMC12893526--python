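# Default synthetic-trial generator configuration.
# Marginals reproduce the source trial's baseline table: 81% women,
# age 45.4 (14.0), years smoking 25.3 (14.6), 96.9% daily smokers,
# 101 (46.2) cigarettes/week, snus 6.2/8.9/84.9%, Fagerstrom 5 (2.2),
# quit attempts 7.2 (13.7), counseling now/past/no 3.1/19.0/77.9%,
# quitline 13.6%, importance 9.4 (1.3), confidence 6.2 (2.5),
# know-how 5.5 (2.6), elective surgery 6.2%.
# Recruitment setting has no reported marginal; 80% online is a simulator
# choice (see docs/methods.md).
n: 1012
block_sizes: [2, 4]
strata: elective_surgery
seed: 0
correlation: []
marginals:
  gender: {kind: categorical, levels: [woman, man], probs: [0.81, 0.19]}
  age: {kind: truncnorm, mean: 45.4, sd: 14.0, lower: 18.0, upper: 95.0}
  years_smoking: {kind: age_linked, mean: 25.3, sd: 14.6, start_lower: 10.0}
  daily_smoker: {kind: flag, prob: 0.969}
  cigarettes_per_week: {kind: truncnorm, mean: 101.0, sd: 46.2, lower: 1.0, upper: .inf}
  snus_use:
    kind: categorical
    levels: [daily, weekly_or_monthly, none]
    probs: [0.062, 0.089, 0.849]
  fagerstrom: {kind: beta, mean: 5.0, sd: 2.2, lower: 0.0, upper: 10.0}
  quit_attempts: {kind: lognormal_count, mean: 7.2, sd: 13.7}
  counseling:
    kind: categorical
    levels: ["no", yes_past, yes_now]
    probs: [0.779, 0.190, 0.031]
  used_quitline: {kind: flag, prob: 0.136}
  importance: {kind: beta, mean: 9.4, sd: 1.3, lower: 0.0, upper: 10.0}
  confidence: {kind: beta, mean: 6.2, sd: 2.5, lower: 0.0, upper: 10.0}
  knowhow: {kind: beta, mean: 5.5, sd: 2.6, lower: 0.0, upper: 10.0}
  elective_surgery: {kind: flag, prob: 0.062}
  setting: {kind: categorical, levels: [primary_care, online], probs: [0.2, 0.8]}
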