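neurons:
  PYR:
    tau_m: 10.5
    tau_ref: 2.0
    C_m: 200.0
    E_l: -70.0
    V_thr: -50.0
    V_reset: -60.0
  PV:
    tau_m: 3.1
    tau_ref: 1.0
    C_m: 200.0
    E_l: -70.0
    V_thr: -50.0
    V_reset: -60.0
  SOM:
    tau_m: 11.8
    tau_ref: 1.0
    C_m: 200.0
    E_l: -70.0
    V_thr: -50.0
    V_reset: -60.0
  VIP:
    tau_m: 10.9
    tau_ref: 1.0
    C_m: 200.0
    E_l: -70.0
    V_thr: -50.0
    V_reset: -60.0
rules:
- pre: PYR
  post: PYR
  probability: 0.1009
  tau_decay: 2.0
  weight_law: log_normal
  g_mean: 0.0
  g_sd: 0.0
- pre: PYR
  post: PV
  probability: 0.1346
  tau_decay: 2.0
  weight_law: gaussian
  g_mean: 0.95
  g_sd: 0.095
- pre: PYR
  post: SOM
  probability: 0.1346
  tau_decay: 2.0
  weight_law: gaussian
  g_mean: 0.29
  g_sd: 0.029
- pre: PYR
  post: VIP
  probability: 0.1346
  tau_decay: 2.0
  weight_law: gaussian
  g_mean: 0.27
  g_sd: 0.027
- pre: PV
  post: PYR
  probability: 0.1689
  tau_decay: 6.4
  weight_law: gaussian
  g_mean: 4.32
  g_sd: 0.432
- pre: PV
  post: PV
  probability: 0.1371
  tau_decay: 4.6
  weight_law: gaussian
  g_mean: 3.51
  g_sd: 0.351
- pre: SOM
  post: PYR
  probability: 0.1689
  tau_decay: 13.1
  weight_law: gaussian
  g_mean: 1.26
  g_sd: 0.126
- pre: SOM
  post: PV
  probability: 0.1174947
  tau_decay: 5.2
  weight_law: gaussian
  g_mean: 1.22
  g_sd: 0.122
- pre: SOM
  post: VIP
  probability: 0.1371
  tau_decay: 10.2
  weight_law: gaussian
  g_mean: 1.18
  g_sd: 0.118
- pre: VIP
  post: SOM
  probability: 0.0856875
  tau_decay: 13.1
  weight_law: gaussian
  g_mean: 0.32
  g_sd: 0.032
ee_weights:
  sigma: 1.0
  mu: -1.3025850929940455
delay_d0:
  PYR: 2.0
  PV: 1.0
  SOM: 1.0
  VIP: 1.0
background:
  kind: background
  rates:
  - 190.0
  - 770.0
  - 100.0
  - 150.0
  g: 10.0
  tau_d: 2.0
  n_fibers: 0
  connection_probability:
  - 1.0
  - 1.0
  - 1.0
  - 1.0
  onset: 0.0
feedforward:
  kind: feedforward
  rates:
  - 25.0
  - 25.0
  - 25.0
  - 25.0
  g: 2.5
  tau_d: 2.0
  n_fibers: 500
  connection_probability:
  - 0.1
  - 0.01
  - 0.01
  - 0.01
  onset: 100.0
simulation:
  dt: 0.1
  duration: 3000.0
  stimulus_onset: 100.0
  discard: 500.0
  n_trials: 50
  master_seed: 0
  scale: 1.0
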