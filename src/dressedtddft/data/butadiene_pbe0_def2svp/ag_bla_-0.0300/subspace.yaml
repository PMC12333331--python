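dipoles:
- - -5.948386172929153e-13
  - 2.5562035655368732e-12
  - -3.6297139745662184e-15
- - -1.420876355616782e-13
  - -2.3230140425958116e-12
  - -2.5033049124161297e-15
double:
- 14
- 15
energy_ground: -155.66664312898024
h_qd:
- -0.09296382363006118
- 0.07932541159777903
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.24551173625734307
- 0.2953912908473982
omega_adia_s1: 0.1945121570486477
omega_adia_s2: 0.1945121570486477
provenance:
  backend: live
  basis: def2-svp
  bla: -0.03
  engine: pyscf
  functional: PBE0
  geometry_checksum: 391b5464f560c6b5d8ab8cbdda57dd91
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
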