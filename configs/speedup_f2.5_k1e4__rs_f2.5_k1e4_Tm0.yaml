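label: rs_f2.5_k1e4_Tm0
output_dir: results/full_scale
units:
  system: reduced Lennard-Jones
  length: a = sigma_P (0.3 nm)
  energy: epsilon (2.74e-21 J)
  mass: m (1.6e-25 kg)
  k_B: 1
protocol:
  n: 16
  force: 2.5
  pore_radius: 1.25
  tether_k: 10000.0
  T_m: 0.0
  T_p: 1.5
  friction: 1.0
  dt: 0.005
  thermalization_steps: 200000
  max_steps: 100000000
  check_stride: 10
  ensemble_size: 1000
  seed: 2016
  membrane_cells: null
  membrane_mass: 1.0
  fail_lateral: 4.0
  fail_steps: 10000
  record_waiting_times: true
  record_reff: false
  reff_stride: 100
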