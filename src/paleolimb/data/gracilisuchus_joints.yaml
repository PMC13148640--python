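# Packaged joint configuration for the Gracilisuchus model.
#
# ROM limits (degrees) are the published figure-caption values; where the
# running text and a figure caption disagree the caption value is used and
# the discrepancy is recorded under `discrepancies` rather than resolved.
# Sign conventions: per-joint anatomical meaning of positive rotation about
# each JCS axis (x = long-axis rotation, y = ab/adduction, z = flex/ext).
# Rotation order is z, then y, then x for every joint.

rotation_order: zyx

cartilage_offsets:
  forearm: {fraction: 0.05, reference: humerus}
  crus: {fraction: 0.10, reference: femur}

reference_lengths_m:
  femur: 0.080          # §ref-pose measurement; 0.078 used as the MMA
  femur_mma: 0.078      # normalizer -- both carried, neither "corrected"
  humerus: 0.057        # not printed; placeholder scaled from femur, configurable
  tibia: 0.070
  metatarsal3: 0.031

joints:
  hip:
    dof: [x, y, z]
    signs: {x: [external LAR, internal LAR], y: [abduction, adduction], z: [extension, flexion]}
    limits: {x: [-60, 60], y: [-10, 90], z: [-65, 65]}
  knee:
    dof: [z]
    signs: {z: [extension, flexion]}
    limits: {z: [-130, 0]}     # extension capped at 0
  ankle:
    dof: [x, y, z]
    signs: {x: [internal LAR, external LAR], y: [adduction, abduction], z: [extension, flexion]}
    limits: {z: [-40, 60]}
  mtp3:
    dof: [z]
    signs: {z: [dorsiflexion, plantarflexion]}
    limits: {z: [-50, 115]}
  shoulder:
    dof: [x, y, z]
    signs: {x: [external LAR, internal LAR], y: [abduction, adduction], z: [extension, flexion]}
    limits: {x: [-60, 60], y: [0, 75], z: [-50, 75]}
  elbow:
    dof: [x, y, z]
    signs: {x: [internal LAR, external LAR], y: [abduction, adduction], z: [flexion, extension]}
    limits: {z: [0, 120]}      # figure caption; running text says 110 total
  wrist:
    dof: [z]
    signs: {z: [palmarflexion, dorsiflexion]}
    limits: {z: [-60, 60]}
  mcp3:
    dof: [z]
    signs: {z: [palmarflexion, dorsiflexion]}
    limits: {z: [-70, 90]}

intervertebral:
  dof: [z, y]
  limits: {z: [-30, 30], y: [-30, 30]}

discrepancies:
  - "elbow flexion/extension: text total 110 deg vs figure caption 0..120; caption used"
  - "hip abduction: text 'a wide 90 deg ROM' vs caption -10..90; caption used"
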