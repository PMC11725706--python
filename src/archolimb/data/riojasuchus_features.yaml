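# Posture-classification feature rows for Riojasuchus tenuisceps:
# this study's model and the earlier published alternative estimates.
# Masses kg, lengths m; com_dimensionless = craniad COM offset / GA distance.
records:
  - taxon: Riojasuchus_this_model
    body_mass_kg: 24.56
    com_craniad_offset_m: 0.0986
    ga_distance_m: 0.355
    forelimb_m: 0.222
    hindlimb_m: 0.320
  - taxon: Riojasuchus_henderson_snively
    body_mass_kg: 13.55
    com_craniad_offset_m: 0.1364
    ga_distance_m: 0.400
    forelimb_m: 0.222
    hindlimb_m: 0.420
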