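dipoles:
- - -5.2082554297432e-13
  - 1.0328262493907873e-12
  - 2.0178542649743583e-14
- - -1.1284802106166308e-13
  - 8.978585563703845e-13
  - 3.91673194711945e-15
double:
- 14
- 15
energy_ground: -155.67968150934865
h_qd:
- -0.08605759307973534
- -0.07248523155199921
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.2635230150521497
- 0.31367606333958703
omega_adia_s1: 0.2172481878536522
omega_adia_s2: 0.2172481878536522
provenance:
  backend: live
  basis: def2-svp
  bla: 0.1
  engine: pyscf
  functional: PBE0
  geometry_checksum: 9ccff693f3f02678ee55772cc782d3d5
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
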