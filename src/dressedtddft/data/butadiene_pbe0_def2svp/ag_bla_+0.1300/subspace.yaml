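dipoles:
- - 6.176262040911509e-13
  - -1.4704175219538413e-12
  - -6.691351789139041e-16
- - 3.2167517915227425e-13
  - -1.3965162599902729e-12
  - 3.777464037539468e-14
double:
- 14
- 15
energy_ground: -155.679871069278
h_qd:
- -0.08435266186137169
- -0.07080430368396111
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.26823569833580974
- 0.3181699519410688
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
- - 13
  - 15
- - 14
  - 16
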