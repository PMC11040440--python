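# Desk-scale demonstration configuration.
#
# A 10,000-child cohort keeps the full pipeline (simulation, IPCW, spatial
# scan, single factors, Causes of Outcome Learning, TMLE validation) within
# a few minutes on one CPU while still recovering the planted hotspot and
# the strongest planted factors.
simulation:
  n_children: 10000
  seed: 1
  # denser demo area so 250 m windows clear the 100-child mask at n=10,000
  area_extent: [0, 0, 1500, 1500]
  hotspot:
    center: [700, 700]
    radius: 200
    excess: 4.0
study:
  split_year: 2011
  seed: 1
  min_count: 100
  window: 250
  step: 10
  cool_hyperparams:
    hidden: 10
    restarts: 3
    epochs: 300
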