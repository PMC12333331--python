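"""Two-electron MO integrals (FCIDUMP-backed) and Slater-Condon coupling
elements between singlet configurations.

Integrals are stored in chemist notation ``(pq|rs)`` — FCIDUMP's native
convention.  The coupling ``H_qD`` is the matrix element of the full
electronic Hamiltonian between the normalized singlet CSF of a single
excitation and the closed-shell determinant of the double; for
configurations differing by two spin-orbitals this involves two-electron
integrals only.  The spin-adaptation convention (alpha+beta over sqrt(2))
is fixed by agreement with a brute-force full-CI oracle, since no closed
formula is printed for it anywhere upstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .excitation_space import DoubleExcitation, SingleExcitation, TruncatedSubspace

__all__ = [
    "MOIntegrals",
    "read_fcidump",
    "write_fcidump",
    "coupling_H_qD",
    "diagonal_elements",
    "chemist_to_physicist",
]


class IntegralError(ValueError):
    pass


@dataclass
class MOIntegrals:
    """Molecular-orbital integrals with full 8-fold symmetry-closed storage.

    ``two_electron[p, q, r, s]`` is the chemist-notation ``(pq|rs)`` in
    hartree.  ``one_electron`` (core Hamiltonian) and ``core_energy`` are
    optional: they are only needed for the diagonal Hamiltonian elements of
    the 0-variant dressing.  ``orbital_indices`` optionally records which
    orbitals of a larger parent set this (active) integral block covers.
    """

    two_electron: np.ndarray
    n_orbitals: int
    one_electron: Optional[np.ndarray] = None
    core_energy: Optional[float] = None
    n_electrons: Optional[int] = None
    orbital_indices: Optional[Tuple[int, ...]] = None

    def __post_init__(self):
        self.two_electron = np.asarray(self.two_electron, dtype=float)
        n = self.n_orbitals
        if self.two_electron.shape != (n, n, n, n):
            raise IntegralError(
                f"two_electron has shape {self.two_electron.shape}, expected {(n,) * 4}"
            )
        if self.one_electron is not None:
            self.one_electron = np.asarray(self.one_electron, dtype=float)
            if self.one_electron.shape != (n, n):
                raise IntegralError("one_electron dimension mismatch")

    def symmetry_violation(self) -> float:
        """Largest deviation from 8-fold permutational symmetry (hartree)."""
        v = self.two_electron
        worst = 0.0
        for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)):
            worst = max(worst, float(np.max(np.abs(v - v.transpose(perm)))))
        return worst


def _close_symmetry(raw: dict, n: int) -> np.ndarray:
    eri = np.zeros((n, n, n, n))
    seen = np.zeros((n, n, n, n), dtype=bool)
    for (p, q, r, s), val in raw.items():
        for a, b, c, d in _eightfold(p, q, r, s):
            if seen[a, b, c, d] and abs(eri[a, b, c, d] - val) > 1e-10:
                raise IntegralError(
                    f"conflicting duplicate entry for ({a}{b}|{c}{d}): "
                    f"{eri[a, b, c, d]} vs {val}"
                )
            eri[a, b, c, d] = val
            seen[a, b, c, d] = True
    return eri


def _eightfold(p, q, r, s):
    return {
        (p, q, r, s),
        (q, p, r, s),
        (p, q, s, r),
        (q, p, s, r),
        (r, s, p, q),
        (s, r, p, q),
        (r, s, q, p),
        (s, r, q, p),
    }


_HEADER_INT = re.compile(r"(NORB|NELEC|MS2)\s*=\s*(-?\d+)", re.IGNORECASE)


def read_fcidump(path) -> MOIntegrals:
    """Parse an FCIDUMP file into symmetry-closed :class:`MOIntegrals`.

    The ``&FCI`` namelist header is handled leniently (NWChem and other
    engine dialects differ only in whitespace and continuation style).
    File indices are 1-based; everything returned is 0-based.  Lines with
    ``k = l = 0`` carry the core Hamiltonian, the all-zero line the core
    energy.
    """
    with open(path) as fh:
        text = fh.read()
    header_match = re.search(r"&FCI(.*?)(?:&END|/|\$END)", text, re.IGNORECASE | re.DOTALL)
    if header_match is None:
        raise IntegralError(f"{path}: no &FCI namelist header found")
    header = header_match.group(1)
    fields = {k.upper(): int(v) for k, v in _HEADER_INT.findall(header)}
    if "NORB" not in fields:
        raise IntegralError(f"{path}: header does not declare NORB")
    n = fields["NORB"]
    n_electrons = fields.get("NELEC")

    body = text[header_match.end() :]
    raw2 = {}
    h1 = np.zeros((n, n))
    has_h1 = False
    core = None
    for line in body.splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise IntegralError(f"{path}: malformed integral line: {line!r}")
        val = float(parts[0].replace("D", "E").replace("d", "e"))
        i, j, k, l = (int(x) for x in parts[1:])
        for idx in (i, j, k, l):
            if idx < 0 or idx > n:
                raise IntegralError(f"{path}: orbital index {idx} outside NORB={n}")
        if i == j == k == l == 0:
            core = val
        elif k == 0 and l == 0:
            if i == 0 or j == 0:
                continue  # orbital-energy lines of some dialects: skip
            h1[i - 1, j - 1] = val
            h1[j - 1, i - 1] = val
            has_h1 = True
        else:
            if 0 in (i, j, k, l):
                raise IntegralError(f"{path}: partial zero index in line: {line!r}")
            raw2[(i - 1, j - 1, k - 1, l - 1)] = val
    eri = _close_symmetry(raw2, n)
    return MOIntegrals(
        two_electron=eri,
        n_orbitals=n,
        one_electron=h1 if has_h1 else None,
        core_energy=core,
        n_electrons=n_electrons,
    )


def write_fcidump(path, integrals: MOIntegrals, n_electrons: Optional[int] = None,
                  ms2: int = 0, threshold: float = 0.0) -> None:
    """Write canonical unique integral entries in FCIDUMP layout (1-based)."""
    n = integrals.n_orbitals
    nelec = n_electrons if n_electrons is not None else (integrals.n_electrons or 0)
    with open(path, "w") as fh:
        fh.write(f"&FCI NORB={n},NELEC={nelec},MS2={ms2},\n")
        fh.write(" ORBSYM=" + "1," * n + "\n")
        fh.write(" ISYM=1,\n")
        fh.write("&END\n")
        eri = integrals.two_electron
        for p in range(n):
            for q in range(p + 1):
                pq = p * (p + 1) // 2 + q
                for r in range(p + 1):
                    for s in range(r + 1):
                        rs = r * (r + 1) // 2 + s
                        if rs > pq:
                            continue
                        val = eri[p, q, r, s]
                        if abs(val) > threshold:
                            fh.write(
                                f"{val:23.16E} {p + 1:4d} {q + 1:4d} {r + 1:4d} {s + 1:4d}\n"
                            )
        if integrals.one_electron is not None:
            h1 = integrals.one_electron
            for p in range(n):
                for q in range(p + 1):
                    if abs(h1[p, q]) > threshold:
                        fh.write(f"{h1[p, q]:23.16E} {p + 1:4d} {q + 1:4d} {0:4d} {0:4d}\n")
        if integrals.core_energy is not None:
            fh.write(f"{integrals.core_energy:23.16E} {0:4d} {0:4d} {0:4d} {0:4d}\n")


def chemist_to_physicist(eri: np.ndarray) -> np.ndarray:
    """Convert chemist (pq|rs) to physicist <pr|qs> ordering."""
    return np.transpose(eri, (0, 2, 1, 3))


# ---------------------------------------------------------------------------
# Slater-Condon machinery on spin-orbital determinants.
#
# Spin orbitals are encoded as 2*p + sigma with sigma in {0: alpha, 1: beta};
# a determinant is a sorted tuple of spin-orbital indices with creation
# operators applied in ascending order.  This canonical phase convention is
# shared with the full-CI oracle so off-diagonal elements are comparable.
# ---------------------------------------------------------------------------


def _spin(so: int) -> int:
    return so & 1


def _spatial(so: int) -> int:
    return so >> 1


def _excite(det: Tuple[int, ...], remove: int, add: int) -> Optional[Tuple[Tuple[int, ...], int]]:
    """Apply a^dag_add a_remove to a canonically ordered determinant."""
    if remove not in det or (add in det and add != remove):
        return None
    lst = list(det)
    i = lst.index(remove)
    phase = (-1) ** i
    del lst[i]
    j = 0
    while j < len(lst) and lst[j] < add:
        j += 1
    phase *= (-1) ** j
    lst.insert(j, add)
    return tuple(lst), phase


def _align(det1: Tuple[int, ...], det2: Tuple[int, ...]):
    """Maximum-coincidence alignment: differing spin orbitals plus parity."""
    s1, s2 = set(det1), set(det2)
    removed = sorted(s1 - s2)
    added = sorted(s2 - s1)
    if len(removed) != len(added):
        return None
    if len(removed) > 2:
        return "far"
    # parity: permutation bringing the differing orbitals of each determinant
    # to the front in matching order
    perm = 0
    for r in removed:
        perm += det1.index(r)
    for a in added:
        perm += det2.index(a)
    phase = (-1) ** perm
    return removed, added, phase


def _so_integral(eri: np.ndarray, a: int, b: int, c: int, d: int) -> float:
    """Antisymmetrized physicist <ab||cd> from spatial chemist integrals."""
    val = 0.0
    if _spin(a) == _spin(c) and _spin(b) == _spin(d):
        val += eri[_spatial(a), _spatial(c), _spatial(b), _spatial(d)]
    if _spin(a) == _spin(d) and _spin(b) == _spin(c):
        val -= eri[_spatial(a), _spatial(d), _spatial(b), _spatial(c)]
    return val


def slater_condon(
    det1: Tuple[int, ...],
    det2: Tuple[int, ...],
    eri: np.ndarray,
    h1: Optional[np.ndarray] = None,
    core_energy: float = 0.0,
) -> float:
    """<det1|H|det2> for canonically ordered spin-orbital determinants."""

    def h(p, q):
        if h1 is None:
            return 0.0
        return h1[_spatial(p), _spatial(q)] if _spin(p) == _spin(q) else 0.0

    res = _align(det1, det2)
    if res is None or res == "far":
        return 0.0
    removed, added, phase = res
    if len(removed) == 0:
        val = core_energy + sum(h(p, p) for p in det1)
        val += 0.5 * sum(
            _so_integral(eri, p, q, p, q) for p in det1 for q in det1
        )
        return val
    if len(removed) == 1:
        m, p = removed[0], added[0]
        val = h(m, p) + sum(_so_integral(eri, m, q, p, q) for q in det1 if q != m)
        return phase * val
    m, n_ = removed
    p, q = added
    return phase * _so_integral(eri, m, n_, p, q)


def _ground_det(n_occupied: int) -> Tuple[int, ...]:
    return tuple(range(2 * n_occupied))


def _single_dets(q: SingleExcitation, n_occupied: int):
    """The alpha- and beta-promoted determinants of q with phases."""
    ground = _ground_det(n_occupied)
    out = []
    for sigma in (0, 1):
        res = _excite(ground, 2 * q.occ + sigma, 2 * q.vir + sigma)
        out.append(res)
    return out


def _double_det(d: DoubleExcitation, n_occupied: int):
    ground = _ground_det(n_occupied)
    det, phase = _excite(ground, 2 * d.occ_pair, 2 * d.vir_pair)
    det, ph2 = _excite(det, 2 * d.occ_pair + 1, 2 * d.vir_pair + 1)
    return det, phase * ph2


def _infer_n_occupied(q: SingleExcitation, d: DoubleExcitation) -> int:
    n_occ = max(q.occ, d.occ_pair) + 1
    if min(q.vir, d.vir_pair) < n_occ:
        raise IntegralError("cannot infer a Fermi level separating occ and vir")
    return n_occ


def coupling_H_qD(
    integrals: MOIntegrals,
    q: SingleExcitation,
    d: DoubleExcitation,
    n_occupied: Optional[int] = None,
) -> float:
    """Hamiltonian coupling between the singlet CSF of ``q`` and the
    closed-shell determinant of ``d``.

    The CSF is (alpha-promoted + beta-promoted)/sqrt(2).  The result is
    independent of the shared core, so ``n_occupied`` may be omitted.
    """
    n_occ = _infer_n_occupied(q, d) if n_occupied is None else n_occupied
    for orb in (q.occ, q.vir, d.occ_pair, d.vir_pair):
        if orb >= integrals.n_orbitals:
            raise IntegralError(
                f"orbital {orb} outside the integral set (n={integrals.n_orbitals})"
            )
    det_d, phase_d = _double_det(d, n_occ)
    total = 0.0
    for res in _single_dets(q, n_occ):
        if res is None:
            continue
        det_q, phase_q = res
        total += phase_q * phase_d * slater_condon(
            det_q, det_d, integrals.two_electron, integrals.one_electron
        )
    return total / np.sqrt(2.0)


def diagonal_elements(
    integrals: MOIntegrals,
    subspace: TruncatedSubspace,
    n_occupied: Optional[int] = None,
):
    """Expectation values (H_qq', H_DD, H_00) in the KS configuration basis.

    Requires one-electron integrals and the core energy; raises otherwise
    ("0-variant unavailable").
    """
    if integrals.one_electron is None or integrals.core_energy is None:
        raise IntegralError(
            "0-variant unavailable: one-electron integrals and core energy "
            "are required for diagonal Hamiltonian elements"
        )
    if n_occupied is None:
        n_occupied = max(
            [s.occ for s in subspace.singles] + [subspace.double.occ_pair]
        ) + 1
    eri = integrals.two_electron
    h1 = integrals.one_electron
    e_core = integrals.core_energy

    def element(bra_dets, ket_dets):
        val = 0.0
        for det_b, ph_b in bra_dets:
            for det_k, ph_k in ket_dets:
                val += ph_b * ph_k * slater_condon(det_b, det_k, eri, h1, e_core)
        return val

    csfs = []
    for s in subspace.singles:
        dets = [r for r in _single_dets(s, n_occupied) if r is not None]
        csfs.append([(det, ph / np.sqrt(2.0)) for det, ph in dets])
    n = subspace.n_singles
    h_qq = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            h_qq[i, j] = element(csfs[i], csfs[j])
    det_d, ph_d = _double_det(subspace.double, n_occupied)
    h_dd = slater_condon(det_d, det_d, eri, h1, e_core)
    ground = _ground_det(n_occupied)
    h_00 = slater_condon(ground, ground, eri, h1, e_core)
    return h_qq, h_dd, h_00
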