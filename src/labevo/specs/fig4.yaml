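# Improving peer review at increasing efficacy (p = 0).
base: {p: 0.0}
axes:
  strategy: [PH, RA, MI]
  G: [10, 85]
  r: [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
replicates: 5
iterations: 100000
equilibrium_window: 10000
seed_base: 0
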