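# Range-check configuration: one monoenergetic spot into the 30 cm water tank.
phantom:
  type: water_tank
  side_cm: 30.0
  spacing_mm: [10.0, 10.0, 1.0]
beam:
  gantry_angle_deg: 0.0
  isocenter_mm: [0.0, 0.0, 0.0]
  spots:
    - {energy_mev: 150.0, weight: 1.0, fwhm_x_mm: 8.0, fwhm_y_mm: 8.0}
engine:
  type: mc
  n_primaries: 100000
  seed: 11
output_dir: protonpbs_out
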