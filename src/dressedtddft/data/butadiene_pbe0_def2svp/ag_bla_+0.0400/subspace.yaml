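dipoles:
- - -2.49629656957142e-13
  - 3.231087016684578e-13
  - -3.0495983492658744e-14
- - -2.0809683291401007e-13
  - 3.1444800373658884e-13
  - -1.3988352375781917e-14
double:
- 14
- 15
energy_ground: -155.67601121516628
h_qd:
- -0.08936904108904381
- -0.07575634500116746
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.25471747328012284
- 0.30498718764925353
omega_adia_s1: 0.20643884182691302
omega_adia_s2: 0.20643884182691302
provenance:
  backend: live
  basis: def2-svp
  bla: 0.04
  engine: pyscf
  functional: PBE0
  geometry_checksum: 770af16259722d52a6b645b3d4c02ac3
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
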