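# Calibrated flare-cycle fixture for study patient 448.
# Times in days, flare at t = 0; rates per day in generic model units.
patient_id: '448'
state0:
  I: 0.1
  P: 0.58
  D: 0.85
  A: 0.1
parameters:
  s_i: 0.2
  s_id: 0.26
  s_a: 0.4
  k_id: 1.0
  k_ip: 0.01
  k_pi: 0.006
  k_pp: 0.02
  k_pd: 0.001
  mu_p: 0.13
  k_dip: 0.01
  k_dp: 0.03
  mu_d: 0.03
  k_ap: 0.035
  k_ad: 0.35
  mu_a: 2.2
  A_inf: 0.45
schedule:
- t_start_days: -180.0
  t_end_days: -120.0
  s_i: 0.2
  s_id: 0.26
  s_a: 0.4
- t_start_days: -120.0
  t_end_days: -60.0
  s_i: 0.2
  s_id: 0.26
  s_a: 0.4
- t_start_days: -60.0
  t_end_days: -14.0
  s_i: 0.02
  s_id: 0.06
  s_a: 0.4
- t_start_days: -14.0
  t_end_days: 0.0
  s_i: 4.5
  s_id: 3.8
  s_a: 0.4
- t_start_days: 0.0
  t_end_days: 14.0
  s_i: 0.06
  s_id: 0.02
  s_a: 5.0
- t_start_days: 14.0
  t_end_days: 42.0
  s_i: 0.06
  s_id: 0.02
  s_a: 10.0
- t_start_days: 42.0
  t_end_days: 60.0
  s_i: 0.06
  s_id: 0.02
  s_a: 2.0
- t_start_days: 60.0
  t_end_days: 120.0
  s_i: 0.06
  s_id: 0.02
  s_a: 2.0
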