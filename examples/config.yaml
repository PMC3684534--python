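# Example trunkreach configuration (all keys optional; these are the defaults).
# Run with:  trunkreach simulate -c examples/config.yaml -o out/
schema_version: 1
body:
  height: 1.78          # m
  mass: 80.0            # kg
  shoulder_offset: 0.2258  # m, trunk rotation axis to shoulder joint
  overrides: {}         # any BodyModel field, e.g. {I_trunk: 0.5}
reach:
  start: [-0.228, 0.25]    # m, shoulder frame at movement onset
  end: [-0.2258, 0.65]
  duration: 0.4            # s
torso:
  amplitude_deg: 40.0   # NOT a printed value: documented package default
  duration: 0.4         # s, synchronous with the reach
  directions: [ccw, cw]
G: [1.0, 1.1, 1.2, 1.3, 1.4, 1.5]   # underestimation gains (G >= 1)
dt: 0.001               # s
seed: 0                 # reserved; the pipeline is deterministic
plan_with_believed: false
torque_interp: cubic
sum_mode: sum
report_lengths: cm
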