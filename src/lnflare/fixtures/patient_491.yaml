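# Calibrated flare-cycle fixture for study patient 491.
# Times in days, flare at t = 0; rates per day in generic model units.
patient_id: '491'
state0:
  I: 0.1
  P: 0.5
  D: 0.38
  A: 0.1
parameters:
  s_i: 0.5
  s_id: 0.6
  s_a: 1.0
  k_id: 1.0
  k_ip: 0.003
  k_pi: 0.05
  k_pp: 0.12
  k_pd: 0.01
  mu_p: 0.33
  k_dip: 0.003
  k_dp: 0.015
  mu_d: 0.035
  k_ap: 0.001
  k_ad: 0.01
  mu_a: 2.2
  A_inf: 0.45
schedule:
- t_start_days: -180.0
  t_end_days: -120.0
  s_i: 0.5
  s_id: 0.6
  s_a: 1.0
- t_start_days: -120.0
  t_end_days: -60.0
  s_i: 0.5
  s_id: 0.6
  s_a: 1.2
- t_start_days: -60.0
  t_end_days: -14.0
  s_i: 0.5
  s_id: 0.6
  s_a: 1.2
- t_start_days: -14.0
  t_end_days: 0.0
  s_i: 0.5
  s_id: 0.6
  s_a: 1.2
- t_start_days: 0.0
  t_end_days: 14.0
  s_i: 0.1
  s_id: 0.1
  s_a: 2.4
- t_start_days: 14.0
  t_end_days: 42.0
  s_i: 0.1
  s_id: 0.1
  s_a: 2.4
- t_start_days: 42.0
  t_end_days: 60.0
  s_i: 0.1
  s_id: 0.1
  s_a: 2.4
- t_start_days: 60.0
  t_end_days: 120.0
  s_i: 0.1
  s_id: 0.1
  s_a: 4.0
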