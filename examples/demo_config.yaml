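# Demo configuration: default study-scale cohorts.
# Run with:  bivshape run-all --config examples/demo_config.yaml --out demo_out
n_arvc: 27
n_control: 21
circumferential_resolution: 24
axial_resolution: 12
sigma_w: 10.0
variance_threshold: 0.8
k: 3
phase: ES
seed: 1
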