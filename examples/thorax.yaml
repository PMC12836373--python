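# Toy thorax case: scanned field covering the CTV, MC engine, all RBE models.
phantom:
  type: thorax
  spacing_mm: 4.0
  seed: 7
beam:
  gantry_angle_deg: 0.0
  isocenter_mm: [0.0, 0.0, 0.0]
  spots:
    - {energy_mev: 95.0,  weight: 1.0, x_mm: -15.0, y_mm: -15.0, fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 95.0,  weight: 1.0, x_mm: -15.0, y_mm: 0.0,   fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 95.0,  weight: 1.0, x_mm: -15.0, y_mm: 15.0,  fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 95.0,  weight: 1.0, x_mm: 0.0,   y_mm: -15.0, fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 95.0,  weight: 1.0, x_mm: 0.0,   y_mm: 0.0,   fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 95.0,  weight: 1.0, x_mm: 0.0,   y_mm: 15.0,  fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 95.0,  weight: 1.0, x_mm: 15.0,  y_mm: -15.0, fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 95.0,  weight: 1.0, x_mm: 15.0,  y_mm: 0.0,   fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 95.0,  weight: 1.0, x_mm: 15.0,  y_mm: 15.0,  fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 105.0, weight: 1.0, x_mm: -15.0, y_mm: -15.0, fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 105.0, weight: 1.0, x_mm: -15.0, y_mm: 0.0,   fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 105.0, weight: 1.0, x_mm: -15.0, y_mm: 15.0,  fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 105.0, weight: 1.0, x_mm: 0.0,   y_mm: -15.0, fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 105.0, weight: 1.0, x_mm: 0.0,   y_mm: 0.0,   fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 105.0, weight: 1.0, x_mm: 0.0,   y_mm: 15.0,  fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 105.0, weight: 1.0, x_mm: 15.0,  y_mm: -15.0, fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 105.0, weight: 1.0, x_mm: 15.0,  y_mm: 0.0,   fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
    - {energy_mev: 105.0, weight: 1.0, x_mm: 15.0,  y_mm: 15.0,  fwhm_x_mm: 12.0, fwhm_y_mm: 12.0}
engine:
  type: mc
  n_primaries: 50000
  seed: 3
radiobiology:
  models: [constant, mcm, mcn, wed]
  alpha_beta_gy: 3.0
  q: 0.434
  n_fractions: 20
  total_course_gy: 40.0
  prescription_structure: ctv
evaluation:
  structures: [ctv, rib, lung]
  dvh: true
  lvh: true
  d_v_cm3: [0.5]
  v_x_gy: [20.0]
output_dir: protonpbs_out
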