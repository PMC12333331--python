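dipoles:
- - -4.80559596767655e-13
  - 1.8027885758524218e-12
  - 2.8384250221805645e-15
- - 2.1498367745843415e-14
  - -1.6660480562455035e-12
  - 1.7329243398373733e-14
double:
- 14
- 15
energy_ground: -155.67387117141305
h_qd:
- -0.09043166910072098
- 0.0768087731824256
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.25196869458898935
- 0.3021837634164776
omega_adia_s1: 0.20295955874360896
omega_adia_s2: 0.20295955874360896
provenance:
  backend: live
  basis: def2-svp
  bla: 0.02
  engine: pyscf
  functional: PBE0
  geometry_checksum: f5cc4af72c9cfccaf48467515b84abc3
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
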