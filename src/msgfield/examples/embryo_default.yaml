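# Default parameters of the six-stage embryo demonstration (all keys optional;
# these mirror the packaged EmbryoConfig defaults).
omega0: 3.0
gamma: 0.05
coupling: 1.0
between_group_attenuation: 0.1
lineage_frequency_split: 0.6
dt: 0.01
stage_horizon: 100.0
compaction_factor: 1.4
coherence_threshold: 0.9
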