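placement_initial:
  SDS: 8.2
  BDS: 9.74
removal:
  SDS: 2.32
  BDS: 2.26
placement_second:
  SDS: 8.45
  BDS: 9.98
daily_use:
  SDS: 12.31
  BDS: 13.27
treatment:
  E4: 5.49
  E5: 12.27
  E6: 4.09
  E7: 12.27
  E8: 3.67
catheters_per_patient:
  SDS: 1.5
  BDS: 1.3
horizon: 14.0
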