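dipoles:
- - -3.3435484997591423e-13
  - 1.5300236735474778e-12
  - -3.404397422392622e-15
- - -9.96984380913755e-14
  - -1.4043038569020722e-12
  - 3.900677298933407e-14
double:
- 14
- 15
energy_ground: -155.67129597447246
h_qd:
- -0.09146776854457636
- 0.07783678899730063
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.2493143909842168
- 0.2994289774054359
omega_adia_s1: 0.19953874585948647
omega_adia_s2: 0.19953874585948647
provenance:
  backend: live
  basis: def2-svp
  bla: 0.0
  engine: pyscf
  functional: PBE0
  geometry_checksum: c0a3bd1772a933a22f73fdba6b3364cf
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
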