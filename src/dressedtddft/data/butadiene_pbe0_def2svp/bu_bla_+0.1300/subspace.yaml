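dipoles:
- - -2.176627338070507
  - 2.116163810736232
  - -2.823231287170631e-16
double:
- 14
- 15
energy_ground: -155.679871069278
h_qd:
- -1.7069848949252665e-14
integral_orbitals:
- 14
- 15
omega_adia:
- 0.22287312803685008
omega_adia_s1: 0.22287312803685008
omega_adia_s2: 0.22287312803685008
provenance:
  backend: live
  basis: def2-svp
  bla: 0.13
  engine: pyscf
  functional: PBE0
  geometry_checksum: bc949722cde100d5e2a8571af2cb4334
  geometry_source: parametric builder
singles:
- - 14
  - 15
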