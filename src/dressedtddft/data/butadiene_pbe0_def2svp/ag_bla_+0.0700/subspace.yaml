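dipoles:
- - 4.912509066812371e-13
  - -1.0996444120152203e-12
  - 5.778795018856928e-16
- - 2.0116415459489639e-13
  - -1.0196239027001432e-12
  - 4.529252497730384e-15
double:
- 14
- 15
energy_ground: -155.67837602915358
h_qd:
- -0.08773328567716057
- -0.07413919230712243
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.2590161056081558
- 0.3092805463210623
omega_adia_s1: 0.21177203957832424
omega_adia_s2: 0.21177203957832424
provenance:
  backend: live
  basis: def2-svp
  bla: 0.07
  engine: pyscf
  functional: PBE0
  geometry_checksum: fa36d2c50dd3c8fcd45f774cc719fe50
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
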