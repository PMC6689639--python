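# Interaction of negative-result publishing and peer review.
base: {}
axes:
  strategy: [PH, RA, MI]
  G: [10, 85]
  p: [0.0, 0.25, 0.5, 0.75, 1.0]
  r: [0.0, 0.25, 0.5, 0.75, 1.0]
replicates: 5
iterations: 100000
equilibrium_window: 10000
seed_base: 0
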