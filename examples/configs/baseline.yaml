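# Baseline run: no growth-factor deprivation, no cytokine.
# Usage: hemodelay run --config examples/configs/baseline.yaml --out traj.csv
scenario: baseline
t_end: 400.0
step: 0.01
stride: 100
initial:
  P: 1000.0
  N: 10000.0
  A: 0.0
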