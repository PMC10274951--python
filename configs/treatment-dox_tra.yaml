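schema_version: 1
seed: 0
domain_edge: 400.0
grid_points: 21
dt: 0.25
total_days: 16.0
vessel_shutoff_day: null
output_cadence_steps: 24
n_cells: 100
initial_cell_state: Q
vessel_file: null
generate_vessels: true
angiogenesis_enabled: false
vegf_vessel_sink: true
substances:
  nutrients:
    enabled: true
    D: 50.0
    lam: 0.0
    bc: neumann
    bc_value: 0.0
    initial: 0.5
  VEGF:
    enabled: false
    D: 10.53
    lam: 0.01
    bc: neumann
    bc_value: 0.0
    initial: 0.0
  DOX:
    enabled: true
    D: 34.61
    lam: 0.012
    bc: neumann
    bc_value: 0.0
    initial: 0.0
  TRA:
    enabled: true
    D: 5.37
    lam: 0.004
    bc: neumann
    bc_value: 0.0
    initial: 0.0
cell_cycle:
  T_SG2: 10.0
  T_G1: 7.0
  u_n_hypoxic: 0.05
  c_Q_SG2: 0.05
  u_n_Q_SG2: 0.1
  lambda_Q_SG2: 60.0
  a_Q_D: 0.001
  b_Q_D: 30.0
  u_n_Q_D: 0.02
  xi_d_Q_D: 0.5
  xi_t_Q_D: 0.5
  xi_dt_Q_D: 6000.0
  c_SG2_SG2: 1.0
  u_d_SG2_SG2: 0.05
  c_SG2_D: 0.001
  u_n_SG2_D: 0.9
  r_H_D: 0.01
  xi_d_H_D: 0.5
  xi_t_H_D: 0.5
  xi_dt_H_D: 6000.0
forces:
  c_repulsion: 10.0
  c_adhesion: 0.4
  eta: 2.0
angiogenesis:
  u_v_threshold: 0.001
  d_tip: 60.0
  d_branch: 40.0
  p_s_rate: 0.04
  w1: 100.0
  w2: 0.5
  w3: 0.2
  g_min: 1.0e-06
  g_stop: 0.01
  speed: 2.0
  split_length: 10.0
  sprout_length: 1.0
  cone_half_angle: 0.5235987755982988
coupling:
  alpha_n: 0.1
  alpha_v: 0.1
  alpha_d: 0.005
  alpha_t: 0.005
  beta_n: 0.002
  beta_v: 0.001
  beta_d: 0.006
  beta_t: 0.008
treatment:
  dox_days:
  - - 8.0
    - 9.0
  tra_days:
  - - 10.0
    - 11.0
  - - 12.0
    - 13.0
  chi_max: 0.75
  tau_up: 12.0
  tau_down: 48.0
vasc_gen:
  domain_lo:
  - -200.0
  - -200.0
  - -200.0
  domain_hi:
  - 200.0
  - 200.0
  - 200.0
  n_parents: 10
  parent_diameter_range:
  - 10.0
  - 22.0
  waviness: 0.15
  exclusion_radius: 70.0
  exclusion_center:
  - 0.0
  - 0.0
  - 0.0
  target_length_density: 8.0e-05
  segment_length: 10.0
  max_extra_vessels: 500
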