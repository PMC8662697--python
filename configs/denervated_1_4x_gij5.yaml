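variant: main
innervation:
  innervated_mask:
  - false
  - false
  - false
  - false
  - false
  - false
  - false
  - false
  - false
  - false
  - false
  - false
  - false
  - false
  - false
  K_NEpn_stim: 0.0
G_ij: 5.0
transport:
  N: 15
  bf: 2.25
  pressure_fold: 1.0
calcium:
  A: 0.2
  B: 0.082
  D: 0.8
  E: 1.0
  F: 0.01
  k1: 1.0
  k2: 0.15
  k3: 1.0
  k_cat: 0.45
  k_d: 0.34
  k_Hr: 1.0
  L: 0.00015
  k_r_i:
  - 0.5
  - 0.5357142857142857
  - 0.5714285714285714
  - 0.6071428571428571
  - 0.6428571428571428
  - 0.6785714285714286
  - 0.7142857142857143
  - 0.75
  - 0.7857142857142857
  - 0.8214285714285714
  - 0.8571428571428571
  - 0.8928571428571428
  - 0.9285714285714286
  - 0.9642857142857142
  - 1.0
  k_IP3_i:
  - 0.5
  - 0.5071428571428571
  - 0.5142857142857142
  - 0.5214285714285715
  - 0.5285714285714286
  - 0.5357142857142857
  - 0.5428571428571428
  - 0.55
  - 0.5571428571428572
  - 0.5642857142857143
  - 0.5714285714285714
  - 0.5785714285714285
  - 0.5857142857142856
  - 0.5928571428571429
  - 0.6
metabolism:
  CaI_GPK: 0.44
  K_CaI_GPK: 3.0
  v0: 0.05
  v_brk: 5.0
  Km_Glyc: 100.0
  Km_Phos: 4000.0
  n_brk: 4.0
  v_CaI_max: 3.0
  Km_CaI: 0.6
  use_Km_CaI: true
  k_LP: 45.0
  k_IP: 26.66
  Phos: 4000.0
  k_export: 0.1
  zonation_weight_i:
  - 1.0
  - 0.9642857142857143
  - 0.9285714285714286
  - 0.8928571428571429
  - 0.8571428571428572
  - 0.8214285714285714
  - 0.7857142857142857
  - 0.75
  - 0.7142857142857143
  - 0.6785714285714286
  - 0.6428571428571429
  - 0.6071428571428572
  - 0.5714285714285714
  - 0.5357142857142858
  - 0.5
systemic:
  G_ref: 2.0
  tau_glu: 1.3
  tau_ins: 0.9
  km_glu: 1.3
  km_ins: 0.9
  n_glu: 2.0
  n_ins: 2.0
  Km_symp: 500.0
  G_symp: 4500.0
  v_Epn: 0.5
  v_NEpn: 1.5
  X_Epn: 6.0
  X_NEpn: 14.0
  adrenal_amplification: 1.4
  v_glu_alt: 0.1
  km_glu_alt: 0.1
  G_au_scale: 2500.0
  k_clear_glucagon: 0.012
  k_clear_insulin: 0.0002
  k_clear_cat: 0.03
  stim_gain_cat: 1.0
  u_G_basal: null
  exercise_multiplier: 3.5
initial:
  CaI0: 0.2
  CaT0: 500.2
  g0: 0.25
  IP30: 0.0001
  r0: 0.5
  Glyc0: 300.0
  GB0: 4600.0
  Ins_B0: 15.0
  Glu_B0: 1.37
  Epn_B0: null
  NEpn_B0: null
exercise_start: 500.0
exercise_duration: 3600.0
t_end: 4100.0
dt_output: 1.0
ca_stimulus_enabled: true
rtol: 1.0e-06
atol: 1.0e-09
seed: null
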