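# Demo configuration for the command-line pipeline (synthetic parameter
# set; not a clinical calibration).
#
#   immunopulse asymptotics   --config examples/demo/config.yaml --out out/
#   immunopulse design-dose   --config examples/demo/config.yaml --out out/
#   immunopulse simulate      --config examples/demo/config.yaml --out out/
#   immunopulse classify      --config examples/demo/config.yaml --out out/
parameters:
  kind: nondimensional
  k_v: 1.0
  k_m: 0.8
  k_CR: 1.2
  mu_D: 0.9
  mu_R: 1.1
  mu_C: 0.7
  k: 1.0
  g: 0.3
  a: 2.0
  V_p: 0.0
schedule:
  V0: 1.0
  delta_t: 1.0
  n_boosts: 120
initial_state:
  V: 0.0
  d_m: 0.0
  d_c: 0.0
  d_r: 0.0
  r: 0.0
  c: 0.0
  p: 0.05
classify:
  x0: 0.05
  t0: 0.0
  burn_in: 120.0
solver:
  horizon: 120.0
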