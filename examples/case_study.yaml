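# Six-parameter cell-behaviour case study: ranges and one-at-a-time
# increments from the published lymphoid-tissue analysis; calibrated
# values are mid-range choices on the increment grid.
parameters:
  - {name: chemoThreshold, lower: 0.0, upper: 1.0, calibrated: 0.3, increment: 0.1}
  - {name: chemoLowerLinearAdjust, lower: 0.015, upper: 0.08, calibrated: 0.045, increment: 0.005}
  - {name: chemoUpperLinearAdjust, lower: 0.1, upper: 0.5, calibrated: 0.3, increment: 0.05}
  - {name: thresholdBindProbability, lower: 0.0, upper: 1.0, calibrated: 0.5, increment: 0.1}
  - {name: vcamSlope, lower: 0.25, upper: 2.0, calibrated: 1.0, increment: 0.25}
  - {name: maxVCAMeffectProbabilityCutoff, lower: 0.0, upper: 1.0, calibrated: 0.5, increment: 0.1}
responses: [Velocity, Displacement]
seed: 42
consistency:
  sample_sizes: [1, 5, 50, 100, 300, 500]
  subset_count: 20
lhs:
  n_sets: 500
  candidates: 20
efast:
  ns: 65
  nr: 3
  m: 4
  dummy_name: dummy
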