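mode: single-point
backend:
  type: model
  seed: 11
  n_singles: 2
dressing:
  variant: a
  tamm_dancoff: false
solver:
  tol: 1.0e-6
  max_iter: 50
states:
  - {label: dark, target: 0}
  - {label: bright, target: 1}
seed: 11
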