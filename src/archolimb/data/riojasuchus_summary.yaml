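# Printed whole-body summary measurements for the Riojasuchus tenuisceps
# model. Lengths in metres, masses in kilograms, angles in degrees.
taxon: Riojasuchus tenuisceps
body_mass_kg: 24.56
com_craniad_offset_m: 0.0986
com_ventrad_offset_m: 0.0594
ga_distance_m: 0.355
hindlimb_length_m: 0.320
forelimb_length_m: 0.222
femur_length_m: 0.179
# Feet extended > 0.11 m craniad to the acetabula in the adjusted
# standing pose; stored as a bare craniocaudal support interval bound.
foot_support_m: [0.0, 0.11]
# Stylopodial minimal diaphyseal circumferences (mm) used for the
# allometric body-mass estimate.
humerus_circumference_mm: 39.0
femur_circumference_mm: 66.0
allometric_mass_kg: 28.33
# Adjusted standing pose used for the COM analysis (degrees).
adjusted_standing_pose:
  hip: {z: -10.0}
  knee: {z: -10.0}
  ankle: {z: -10.0}
  elbow: {z: -10.0}
  shoulder: {z: 10.0}
  wrist: {z: 10.0}
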