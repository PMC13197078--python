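# Reference scenario: a legume host (body C:N 11, e.g. hairy vetch
# clover) trading with a Rhizobium symbiont (body C:N 11, lower end of
# the R. meliloti range) in nitrate-dominated aerobic soil (s=1).
# Host budget 9 mol ATP/time gives a box height h = b_L/a_LC = 1, so
# all allocations are fractions of the host's fixed C.
# The "median" exchange policy anchors r at the midpoint of the
# nitrate-cost interval, r = 1.69; the sweep below also covers the
# range ends r = 1.51 and r = 1.88.
organisms:
  host:
    c: 11.0
    budget_b: 9.0
    label: legume (hairy vetch clover)
  symbiont:
    c: 11.0
    budget_b: 16.0
    label: Rhizobium meliloti

costs: defaults
soil_state: 1

exchange:
  policy: median

sweep:
  c_L: [11.0, 26.0, 0.01]
  c_R: [11.0, 12.0, 0.01]
  r_values: [1.51, 1.69, 1.88]

dynamics:
  sigma0: 0.0
  t_end: 8.0
  rate_constant: 1.0

seed: 0
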