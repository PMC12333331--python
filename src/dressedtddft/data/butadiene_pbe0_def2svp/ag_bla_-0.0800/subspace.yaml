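dipoles:
- - -5.475352218546451e-14
  - -5.328069538496544e-14
  - 4.737836800762764e-16
- - -1.185202062942553e-13
  - -3.832593151644902e-14
  - 1.609498066135265e-14
double:
- 14
- 15
energy_ground: -155.6568646581311
h_qd:
- -0.09526886253568205
- -0.08163360767827563
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.2396568183912962
- 0.2889281408111111
omega_adia_s1: 0.18639310015864868
omega_adia_s2: 0.18639310015864868
provenance:
  backend: live
  basis: def2-svp
  bla: -0.08
  engine: pyscf
  functional: PBE0
  geometry_checksum: 3e6e07360cab47203d8121abe07fc324
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
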