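dipoles:
- - -3.596669101616964e-13
  - 1.767133226717615e-12
  - 6.677602658311598e-17
- - -2.987947460336166e-13
  - -1.5408408350221199e-12
  - 2.5398450659585102e-14
double:
- 14
- 15
energy_ground: -155.6610730338377
h_qd:
- -0.09437820295273446
- 0.08073906176329287
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.24192584219113572
- 0.2914720400333341
omega_adia_s1: 0.1896038418314492
omega_adia_s2: 0.1896038418314492
provenance:
  backend: live
  basis: def2-svp
  bla: -0.06
  engine: pyscf
  functional: PBE0
  geometry_checksum: 827cd8c2946c6be06d1b60dd106df3d1
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
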