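# Two-compartment phantom, 5x5x5 mm voxel inside the outer (GABA) bottle
phantom:
  grid_step_mm: 1.0
  compartments:
    - bounds_mm: [[-15, 15], [-15, 15], [-15, 15]]
      mixture: {GABA: 100.0}
    - bounds_mm: [[-5, 5], [-5, 5], [-5, 5]]
      mixture: {Prop: 100.0}
voxel: {center_mm: [0, 10, 0], size_mm: [5, 5, 5]}
context: {b0_t: 7.0, carrier_ppm: 4.7}
sequence: {name: psyche-isis, beta_deg: 15.0, sweep_hz: 10000.0, chirp_duration_s: 0.015, tau_s: 0.010, n_increments: 32, n_z: 16}
acquisition: {n_points: 80, dwell_s: 0.00025, t2_s: 0.3}
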