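# Example run configuration. Every field is optional; omitted fields take
# the nominal defaults listed in docs/methods.md. Unknown keys are rejected.

model:
  # high-chemosensitivity regime used by the scheduling examples
  beta1: 0.6
  beta: 0.2

initial:
  n1: 280.0   # sensitive volume, mm^3
  n2: 20.0    # resistant volume, mm^3
  k: 650.0    # carrying capacity, mm^3

weights:
  omega1: 5.0
  omega2: 25.0
  eta1: 1.0
  eta2: 5.0
  xi: 1000.0
  epsilon: 10.0
  theta: 0.0

survival:
  n_crit: 8000.0
  t_max: 1000.0

transcription:
  n_intervals: 400
  horizon: 14.0

seed: 1
output_dir: chemosched-out
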