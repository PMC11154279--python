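# Demo run: 10 x 10 mm^2 microbeam field on a 20 x 40 x 20 mm^3 PMMA slab
# resting on the mouse bed position (4 mm collimator gap).  The deterministic
# engine keeps the demo fast; switch execution.engine to "mc" for the Monte
# Carlo path.  output_factor is the machine calibration constant converting
# engine dose units (keV/g per history) to Gy/min.
geometry:
  sd_mm: 212.0
  slit_um: 30.0
  ctc_um: 400.0
  field_mm: [10.0, 10.0]
  sigma_mm: 0.58
spectrum:
  kvp: 225
  filtration_mm_al: 1.0
phantom:
  kind: slab
  dims_mm: [20.0, 40.0, 20.0]
  material: pmma
  voxel_mm: 1.0
  roi_depth_mm: [5.0, 10.0]
  roi_lateral_mm: 8.0   # keep the target inside the 10 mm field
plan:
  prescription_gy: 20.0
  roi: target
execution:
  seed: 1
  histories: 100000
  engine: deterministic
  gap_mm: 4.0
  # machine calibration: Gy/min per engine dose unit (keV/g per unit
  # collimator-plane fluence), set once against the measured reference peak
  # dose rate in the brain target
  output_factor: 3.404
output_dir: mrtplan_out
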