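# Calibrated flare-cycle fixture for study patient 416.
# Times in days, flare at t = 0; rates per day in generic model units.
patient_id: '416'
state0:
  I: 0.1
  P: 0.4
  D: 1.7
  A: 0.1
parameters:
  s_i: 0.002
  s_id: 0.005
  s_a: 0.05
  k_id: 1.0
  k_ip: 0.025
  k_pi: 0.13
  k_pp: 0.02
  k_pd: 0.001
  mu_p: 0.06
  k_dip: 0.025
  k_dp: 0.27
  mu_d: 0.04
  k_ap: 0.022
  k_ad: 0.22
  mu_a: 2.2
  A_inf: 0.45
schedule:
- t_start_days: -180.0
  t_end_days: -120.0
  s_i: 0.002
  s_id: 0.005
  s_a: 0.05
- t_start_days: -120.0
  t_end_days: -60.0
  s_i: 0.001
  s_id: 0.003
  s_a: 0.1
- t_start_days: -60.0
  t_end_days: -14.0
  s_i: 0.005
  s_id: 0.015
  s_a: 0.05
- t_start_days: -14.0
  t_end_days: 0.0
  s_i: 0.005
  s_id: 0.015
  s_a: 0.05
- t_start_days: 0.0
  t_end_days: 14.0
  s_i: 0.001
  s_id: 0.002
  s_a: 0.3
- t_start_days: 14.0
  t_end_days: 42.0
  s_i: 0.001
  s_id: 0.002
  s_a: 0.3
- t_start_days: 42.0
  t_end_days: 60.0
  s_i: 0.001
  s_id: 0.002
  s_a: 0.3
- t_start_days: 60.0
  t_end_days: 120.0
  s_i: 0.005
  s_id: 0.012
  s_a: 0.1
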