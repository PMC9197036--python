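n_per_arm:
  SDS: 495
  BDS: 494
sojourn_mean_s1:
  SDS: 1.8269
  BDS: 2.1226
sojourn_mean_s2:
  SDS: 3.59
  BDS: 3.85
sojourn_mean_s3:
  SDS: 7.79
  BDS: 7.77
p_unscheduled:
  SDS: 0.47474747474747475
  BDS: 0.3481781376518219
p_death:
  SDS: 0.010101010101010102
  BDS: 0.016194331983805668
event_mix_scheduled:
- 0.3333333333333333
- 0.3333333333333333
- 0.3333333333333333
event_mix_unscheduled:
- 0.2
- 0.2
- 0.2
- 0.2
- 0.2
horizon: 14.0
sojourn_family_s1: gamma
sojourn_shape_s1: 2.0
sojourn_family_late: exponential
sojourn_shape_late: 1.0
seed: 0
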