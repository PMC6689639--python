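# Pure funding strategies without open-science improvements (p = r = 0),
# across grant sizes. Desk-scale reduction of the full protocol.
base: {p: 0.0, r: 0.0}
axes:
  strategy: [PH, RA, MI]
  G: [10, 35, 60, 85]
replicates: 5
iterations: 100000
equilibrium_window: 10000
seed_base: 0
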