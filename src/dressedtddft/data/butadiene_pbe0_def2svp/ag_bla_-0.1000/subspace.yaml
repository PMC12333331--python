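dipoles:
- - 1.3465381919563042e-13
  - -5.631435569494673e-13
  - -3.6620655453858295e-15
- - 1.2047033297046543e-13
  - 4.792633567779168e-13
  - -1.310332652080175e-14
double:
- 14
- 15
energy_ground: -155.6522687980485
h_qd:
- -0.09611276396485188
- 0.08248539229757444
integral_orbitals:
- 13
- 14
- 15
- 16
omega_adia:
- 0.23748578442973392
- 0.2864418468627388
omega_adia_s1: 0.18322846411077423
omega_adia_s2: 0.18322846411077423
provenance:
  backend: live
  basis: def2-svp
  bla: -0.1
  engine: pyscf
  functional: PBE0
  geometry_checksum: 3ad3f333d5b06b7db56c756da3764135
  geometry_source: parametric builder
singles:
- - 13
  - 15
- - 14
  - 16
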