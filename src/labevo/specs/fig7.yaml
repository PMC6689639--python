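# Modified lottery ML(A): uniform award over applicants with alpha <= A,
# with coupled open-science axis p = r.
base: {strategy: ML}
axes:
  A: [0.1, 0.2, 0.3, 0.5, 0.7, 1.0]
  "p,r": [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
  G: [10, 85]
replicates: 5
iterations: 100000
equilibrium_window: 10000
seed_base: 0
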