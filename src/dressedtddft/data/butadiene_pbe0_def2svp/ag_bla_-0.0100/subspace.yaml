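dipoles:
- - -8.340188366633446e-14
  - -6.239711535135804e-15
  - 2.1883887585963008e-15
- - 8.433285864334999e-14
  - -7.222576606665586e-14
  - -4.397352021036911e-16
double:
- 14
- 15
energy_ground: -155.6698489863717
h_qd:
- -0.09197468800868992
- -0.07834056221256822
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.24802290560247525
- 0.29807028428622917
omega_adia_s1: 0.1978495607498681
omega_adia_s2: 0.1978495607498681
provenance:
  backend: live
  basis: def2-svp
  bla: -0.01
  engine: pyscf
  functional: PBE0
  geometry_checksum: 806ebc971f5e35b0dfaa638b70218c7e
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
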