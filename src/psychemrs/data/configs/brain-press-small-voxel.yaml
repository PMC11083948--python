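# PRESS baseline on the brain metabolite phantom, 5x5x5 mm voxel, TE 40 ms
phantom:
  grid_step_mm: 1.0
  compartments:
    - bounds_mm: [[-10, 10], [-10, 10], [-10, 10]]
      mixture: {NAA: 1.0, Cr: 1.0, Cho: 1.0, mI: 1.0, Tau: 1.0, Asp: 1.0, GABA: 1.0}
voxel: {center_mm: [0, 0, 0], size_mm: [5, 5, 5]}
context: {b0_t: 7.0, carrier_ppm: 4.7}
sequence: {name: press, te1_s: 0.02, te2_s: 0.02}
acquisition: {n_points: 2048, dwell_s: 0.00025, t2_s: 0.3}
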