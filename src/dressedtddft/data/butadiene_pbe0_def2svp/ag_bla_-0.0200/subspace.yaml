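dipoles:
- - 1.6452138777062234e-13
  - -9.660385842061848e-13
  - -3.732376605550796e-15
- - -5.765044064363699e-14
  - 9.6856978842076e-13
  - -3.493068845831672e-15
double:
- 14
- 15
energy_ground: -155.66829760383686
h_qd:
- -0.09247353866789211
- 0.07883692064224244
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.2467553232271829
- 0.2967243196299216
omega_adia_s1: 0.19617413189598415
omega_adia_s2: 0.19617413189598415
provenance:
  backend: live
  basis: def2-svp
  bla: -0.02
  engine: pyscf
  functional: PBE0
  geometry_checksum: 6df3d89420143f24f34c51ce876d0202
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
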