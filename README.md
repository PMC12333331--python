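# dressedtddft

Frequency-dependent **dressed TDDFT** beyond the Tamm-Dancoff
approximation: an *a posteriori* correction to adiabatic linear-response
TDDFT (ATDDFT) for states in which several Kohn-Sham single excitations
mix with one double excitation — the classic example being the dark
2<sup>1</sup>Ag state of s-trans-butadiene, whose potential-energy curve
crosses the bright 1<sup>1</sup>Bu along the bond-length-alternation
(BLA) coordinate.

The package implements:

* **Truncated excitation subspaces** (`excitation_space`): the chosen
  singles, one same-orbital-pair double, KS and ATDDFT frequencies,
  adiabatic response blocks A/B, couplings and transition dipoles.
* **Coupling elements** (`matrix_elements`): FCIDUMP reader/writer with
  full 8-fold symmetry closure, and the Hamiltonian coupling `H_qD`
  between the singlet CSF of a single excitation and the closed-shell
  doubly excited determinant, via Slater-Condon rules (validated against
  a brute-force full-CI oracle).
* **Dressing kernels** (`dressing`): the additive frequency-dependent
  corrections `X(omega)` in three variants — `S` (bare KS frequencies in
  shift and pole), `a` (ATDDFT frequencies), `zero` (diagonal Hamiltonian
  elements) — plus the scalar dressed-SMA kernel, all with closed-form
  derivatives with respect to omega^2.
* **Self-consistent solver** (`solver`): dressed response matrices
  `A + 2X`, `B + 2X`, symmetric folding
  `(A-B)^{1/2}(A+B)(A-B)^{1/2}`, fixed-point iteration with
  overlap-based root following, eigenvector normalization
  `G^T(1 - dOmega/domega^2)G = 1` (the `|G|^2` single-excitation
  weight), and sum-rule-preserving oscillator strengths.
* **Backends** (`backends`): a seeded synthetic model generator whose
  couplings are recomputed from its own random integrals, a plain-text
  file backend (documented directory layout), and an optional live
  adapter driving pyscf (ground-state SCF + adiabatic response, subspace
  blocks extracted by probing the response matvec).
* **BLA scans** (`scan`): a parametric s-trans-butadiene builder,
  per-geometry dressed/adiabatic solves with character tracking, and
  crossing location by linear interpolation of the gap sign change.
* **CLI** (`cli`): `dressedtddft demo|single|scan`.
* **CI oracles** (`ci_oracle`): test-only brute-force references
  (squared shifted Hamiltonian diagonalization, scalar effective
  frequency map, dense full CI on at most 4 orbitals).

## CLI

```bash
# synthetic end-to-end demo (byte-identical report for a fixed seed)
dressedtddft demo --seed 3 --variant a --out report.json

# single point from a YAML config
dressedtddft single --config examples/single_model.yaml --out report.json

# BLA scan over precomputed file-backend bundles, with crossing summary
dressedtddft scan --config examples/scan_fixture.yaml --out-dir scan_out
```

A single-point config looks like

```yaml
mode: single-point
backend: {type: directory, path: src/dressedtddft/data/butadiene_pbe0_def2svp/ag_bla_+0.1300}
dressing: {variant: a}
solver: {tol: 1.0e-6, max_iter: 50}
states:
  - {label: 2Ag, target: 0}
```

Energies are reported in eV (internally everything is hartree);
iteration logging is in meV (`-v`).

## Shipped data

`src/dressedtddft/data/butadiene_pbe0_def2svp/` holds plain-text subspace
bundles (orbital energies, adiabatic A/B blocks, ATDDFT frequencies,
FCIDUMP integrals over the frontier orbitals, transition dipoles)
extracted with PBE0/def2-SVP over parametric-builder butadiene geometries:
the 2x2 Ag subspace (HOMO-1 -> LUMO, HOMO -> LUMO+1 mixed with
HOMO^2 -> LUMO^2) along a BLA scan, and a 1x1 HOMO -> LUMO (Bu) bundle at
the equilibrium-region point.  They are regenerated with

```bash
python scripts/make_fixtures.py        # requires the 'live' extra
```

Couplings stored in a bundle are revalidated against its own FCIDUMP on
every load.  Note the builder geometries are a documented stand-in;
published crossing coordinates refer to an externally published geometry
set, which can be supplied as XYZ files for exact reproduction
(`scripts/reproduce_bla_scan.py`).

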