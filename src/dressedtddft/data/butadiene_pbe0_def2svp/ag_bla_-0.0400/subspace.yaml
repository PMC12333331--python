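dipoles:
- - -9.665967723382706e-13
  - 4.061173564010841e-12
  - 6.880574871803899e-16
- - -3.2528813151115254e-13
  - -3.6533822325350766e-12
  - 3.080479649169404e-14
double:
- 14
- 15
energy_ground: -155.66488678767575
h_qd:
- -0.0934450383032178
- 0.07980557601291254
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.24429223525800292
- 0.2940714148920126
omega_adia_s1: 0.19286332757569888
omega_adia_s2: 0.19286332757569888
provenance:
  backend: live
  basis: def2-svp
  bla: -0.04
  engine: pyscf
  functional: PBE0
  geometry_checksum: d9158c9556a9437fa247c6cad09eebe1
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
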