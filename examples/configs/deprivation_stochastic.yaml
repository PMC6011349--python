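# Growth-factor deprivation with the stochastic reading of the loss
# multiplier (drawn per step from U(0, 1)); the seed makes the run
# exactly reproducible.
# Usage: hemodelay run --config examples/configs/deprivation_stochastic.yaml
scenario: deprivation
deprivation_mode: stochastic
seed: 1
t_end: 400.0
step: 0.01
stride: 100
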