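# Simulation presets consumed by `glaufuse simulate`.
# "paper" mirrors the emulated study composition; "normative" sizes the
# separate healthy cohort used for normative-database construction.
paper:
  n_healthy: 125
  n_glaucoma: 135
  severity_counts:
    EARLY: 49
    MODERATE: 32
    ADVANCED: 54
normative:
  n: 500
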