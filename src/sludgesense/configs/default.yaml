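plant:
  V: 2000.0
  Q_bar: 3000.0
  D: 0.0625
  kLa: 0.1875
  X5_max: 4.217491
  r_recycle: 1.652242
  eps_waste: 0.0
  Ts: 0.02390438247011952
  COD_max: 150.0
  Is: 30.0
  TN_in: 30.0
kinetics:
  mu_max_H: 0.026327
  mu_max_A: 0.01
  b_H: 0.025833333333333333
  b_A: 0.043838
  k_h: 0.047753
  eta_g: 0.8
  eta_h: 0.4
  K_S: 500.0
  K_OH: 0.2
  K_OA: 1.87993
  K_NH: 1.0
  K_NO: 0.5
  K_X: 0.03
  S_NH_const: 20.0
  S_NO_const: 5.0
stoichiometry:
  Y_H: 0.67
  Y_A: 0.24
  f_p: 0.08
influent:
  base_X1_in: 245.0
  base_X2_in: 45.0
  base_X3_in: 22.0
  base_X4_in: 1.5
  base_X5_in: 2.5
  base_D: 0.0625
  diurnal_amplitude: 0.869
  diurnal_amplitude_D: 0.2538
  diurnal_phase_h: 6.0
  noise_sd: 0.015
  noise_sd_D: 0.01
  noise_sd_X5_in: 0.45
  noise_sd_X4_in: 0.0
  noise_sd_X3_in: 0.0
  noise_corr: 0.992
  measurement_noise_sd: 0.01
  warmup_h: 240.0
  seed: 20231117
dataset:
  n_samples: 5020
  lookback: 7
  n_trainval: 4500
  train_fraction: 0.8
lstm:
  batch_size: 128
  lookback: 7
  epochs: 700
  dropout_rate: 0.1
  learning_rate: 0.001
  cells_per_layer:
  - 128
  - 64
  dense_relu_head: false
  seed: 0
ffnn:
  n_hidden: 128
  hidden_activation: tanh
  input_mode: current
  lm_lambda0: 0.01
  lm_lambda_factor: 10.0
  lm_lambda_min: 1.0e-12
  lm_lambda_max: 10000000000.0
  max_iters: 60
  tol_grad: 1.0e-06
  max_train_samples: 0
  seed: 0
evaluation:
  COD_max: 150.0
  Is: 30.0
seed: 0
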