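# IM-BECT plan of the wavy-slab phantom: 16 MeV, R90 = 5 cm, 10x10 cm field.
# The non-modulated (BECT) plan is the same sequence without the last four
# operators.
beam:
  energy_mev: 16.0
  r90_cm: 5.0
  sigma_theta0_rad: 0.03
  xray_tail_pct: 3.0
aperture:
  width_cm: 10.0
  height_cm: 10.0
phantom:
  kind: wavy_slab
  ssd_cm: 100.0
  ptv_distal_amplitude_cm: 0.5
  ptv_period_cm: 8.0
  ptv_distal_depth_cm: 3.0
  ptv_half_width_cm: [3.0, 3.0]
sequence:
  - {op: create, percent: 90, inner_margin: 0.7}
  - {op: smooth, exp_mult: 2, radius_mult: 1}
  - {op: isodose_shift, inner_margin: 0.5}
  - {op: smooth, exp_mult: 2, radius_mult: 1}
  - {op: isodose_shift, inner_margin: 0.5}
  - {op: smooth, exp_mult: 2, radius_mult: 1}
  - {op: truncate}
  - {op: specified_shift, delta: -0.1}
  - {op: intensity_modulation, margin: 0.5}
  - {op: isodose_shift, inner_margin: 0.5}
  - {op: smooth, exp_mult: 2, radius_mult: 1}
  - {op: specified_shift, delta: -0.1}
modulation:
  irf_min: 0.8
  irf_max: 1.0
output_dir: out
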