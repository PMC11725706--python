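# Joint range-of-motion limits estimated for Riojasuchus tenuisceps.
# Angles in degrees; limits inclusive. Flexion/extension about the JCS
# z-axis (extension positive), ab/adduction about y, long-axis rotation
# (LAR) about x (external positive). The y interval stores the printed
# pair (abduction bound -10, adduction bound 70) as [-10, 70].
units: degrees
taxon: Riojasuchus tenuisceps
joints:
  hip:
    dofs: [x, y, z]
    rom:
      z: [-65.0, 55.0]   # flexion -65 to extension 55
      y: [-10.0, 70.0]   # abduction -10 to adduction 70
      x: [-50.0, 50.0]   # internal -50 to external 50 LAR
  knee:
    dofs: [z]
    rom:
      z: [-110.0, 0.0]   # flexion -110; extension 0
  ankle:
    dofs: [z]
    rom:
      z: [-50.0, 30.0]   # flexion -50 to extension 30
  mtp3:
    dofs: [z]
    rom:
      z: [-80.0, 50.0]   # plantarflexion -80 to dorsiflexion 50
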