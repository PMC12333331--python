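# BLA scan over the shipped PBE0/def2-SVP butadiene bundles.
# 2Ag: dressed (variant a) lower root of the 2x2 Ag subspace.
# 1Bu: the ATDDFT state of the double's constituent single (HOMO->LUMO).
mode: scan
backend:
  type: directory
  directories:
    -0.10: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_-0.1000
    -0.08: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_-0.0800
    -0.06: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_-0.0600
    -0.04: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_-0.0400
    -0.03: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_-0.0300
    -0.02: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_-0.0200
    -0.01: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_-0.0100
    0.00: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_+0.0000
    0.02: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_+0.0200
    0.04: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_+0.0400
    0.07: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_+0.0700
    0.10: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_+0.1000
    0.13: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_+0.1300
dressing:
  variant: a
solver:
  tol: 1.0e-6
  max_iter: 100
states:
  - {label: 2Ag, target: 0, dressed: true}
  - {label: 1Bu, target: adiabatic_s1, dressed: false}
seed: 0
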