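"""Truncated excitation subspace: the singles, the double, and everything
the dressing consumes.

Orbital indexing is 0-based throughout the package; FCIDUMP's 1-based
indices are converted at the I/O boundary only.  Kohn-Sham excitation
frequencies (``nu``) are always recomputed from orbital energies, never
accepted as free inputs, so stored and derived values cannot drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "OrbitalSpectrum",
    "SingleExcitation",
    "DoubleExcitation",
    "DiagonalElements",
    "TruncatedSubspace",
    "build_subspace",
    "select_double",
]


class SubspaceError(ValueError):
    """Raised when subspace inputs violate a structural invariant."""


@dataclass(frozen=True)
class OrbitalSpectrum:
    """Kohn-Sham orbital energies for a closed-shell reference.

    Parameters
    ----------
    orbital_energies:
        Energies in hartree, occupied block first, each block ascending.
    n_occupied:
        Number of doubly occupied spatial orbitals.
    """

    orbital_energies: np.ndarray
    n_occupied: int

    def __post_init__(self):
        energies = np.asarray(self.orbital_energies, dtype=float)
        object.__setattr__(self, "orbital_energies", energies)
        n = energies.size
        if not 0 < self.n_occupied < n:
            raise SubspaceError(
                f"n_occupied={self.n_occupied} must lie strictly inside (0, {n})"
            )
        occ = energies[: self.n_occupied]
        vir = energies[self.n_occupied :]
        if np.any(np.diff(occ) < 0) or np.any(np.diff(vir) < 0):
            raise SubspaceError(
                "orbital energies must be ascending within the occupied and "
                "virtual blocks"
            )

    @property
    def n_orbitals(self) -> int:
        return self.orbital_energies.size

    @property
    def labels(self) -> Mapping[str, int]:
        """Named frontier orbitals mapped to 0-based indices."""
        homo = self.n_occupied - 1
        out = {"HOMO": homo, "LUMO": self.n_occupied}
        if homo >= 1:
            out["HOMO-1"] = homo - 1
        if self.n_occupied + 1 < self.n_orbitals:
            out["LUMO+1"] = self.n_occupied + 1
        return out

    def resolve(self, label_or_index) -> int:
        """Resolve an orbital given either an integer index or a frontier label."""
        if isinstance(label_or_index, str):
            key = label_or_index.strip().upper().replace(" ", "")
            labels = {k.upper(): v for k, v in self.labels.items()}
            if key not in labels:
                raise SubspaceError(f"unknown orbital label {label_or_index!r}")
            return labels[key]
        return int(label_or_index)

    def nu(self, occ: int, vir: int) -> float:
        """KS frequency of the promotion occ -> vir (orbital-energy difference)."""
        self._check_sides(occ, vir)
        return float(self.orbital_energies[vir] - self.orbital_energies[occ])

    def _check_sides(self, occ: int, vir: int) -> None:
        if not (0 <= occ < self.n_occupied):
            raise SubspaceError(f"orbital {occ} is not occupied (n_occ={self.n_occupied})")
        if not (self.n_occupied <= vir < self.n_orbitals):
            raise SubspaceError(f"orbital {vir} is not virtual (n_occ={self.n_occupied})")


@dataclass(frozen=True)
class SingleExcitation:
    """One-electron promotion occ -> vir with KS frequency ``nu_q``."""

    occ: int
    vir: int
    nu_q: float

    def __post_init__(self):
        if self.nu_q <= 0:
            raise SubspaceError(
                f"single excitation {self.occ}->{self.vir} has non-positive "
                f"KS frequency {self.nu_q}"
            )


@dataclass(frozen=True)
class DoubleExcitation:
    """Two-electron promotion occ_pair^2 -> vir_pair^2.

    Only same-orbital-pair doubles are supported; ``s1`` and ``s2`` are the
    (identical) constituent single excitations and ``nu_D = nu_s1 + nu_s2``.
    """

    occ_pair: int
    vir_pair: int
    s1: SingleExcitation
    s2: SingleExcitation
    nu_D: float

    def __post_init__(self):
        if (self.s1.occ, self.s1.vir) != (self.occ_pair, self.vir_pair) or (
            self.s2.occ,
            self.s2.vir,
        ) != (self.occ_pair, self.vir_pair):
            raise SubspaceError(
                "only same-orbital-pair doubles (p^2 -> r^2) are supported; "
                "constituent singles must both be occ_pair -> vir_pair"
            )
        expected = self.s1.nu_q + self.s2.nu_q
        if abs(self.nu_D - expected) > 1e-12:
            raise SubspaceError(
                f"nu_D={self.nu_D} inconsistent with nu_s1+nu_s2={expected}"
            )


@dataclass(frozen=True)
class DiagonalElements:
    """Diagonal Hamiltonian data needed only by the 0-variant dressing."""

    h_qq: np.ndarray  # <CSF_q|H|CSF_q'> over subspace singles (hartree)
    h_dd: float
    h_00: float

    def __post_init__(self):
        object.__setattr__(self, "h_qq", np.asarray(self.h_qq, dtype=float))


@dataclass(frozen=True)
class TruncatedSubspace:
    """All per-excitation quantities consumed by the dressing and solver.

    ``a_adia``/``b_adia`` are the adiabatic response blocks over the ordered
    singles; ``h_qd`` is the Hamiltonian coupling vector to the double;
    ``omega_adia`` holds the ATDDFT frequency assigned to each single, and
    ``omega_adia_s1/s2`` those of the double's constituent singles.
    """

    singles: Tuple[SingleExcitation, ...]
    double: DoubleExcitation
    a_adia: np.ndarray
    b_adia: np.ndarray
    h_qd: np.ndarray
    omega_adia: np.ndarray
    omega_adia_s1: float
    omega_adia_s2: float
    dipoles: Optional[np.ndarray] = None
    diag_elements: Optional[DiagonalElements] = None

    def __post_init__(self):
        object.__setattr__(self, "singles", tuple(self.singles))
        for name in ("a_adia", "b_adia", "h_qd", "omega_adia"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.dipoles is not None:
            object.__setattr__(self, "dipoles", np.asarray(self.dipoles, dtype=float))

    @property
    def n_singles(self) -> int:
        return len(self.singles)

    @property
    def nu(self) -> np.ndarray:
        """KS frequencies of the subspace singles (hartree)."""
        return np.array([s.nu_q for s in self.singles])

    @property
    def nu_d(self) -> float:
        return self.double.nu_D

    def validate(self, sym_tol: float = 1e-7) -> None:
        n = self.n_singles
        for name in ("a_adia", "b_adia"):
            m = getattr(self, name)
            if m.shape != (n, n):
                raise SubspaceError(f"{name} has shape {m.shape}, expected {(n, n)}")
            asym = float(np.max(np.abs(m - m.T))) if n else 0.0
            if asym > sym_tol:
                raise SubspaceError(
                    f"{name} asymmetric beyond tolerance: max |M-M^T| = {asym:.3e}"
                )
        if self.h_qd.shape != (n,):
            raise SubspaceError(f"h_qd has shape {self.h_qd.shape}, expected ({n},)")
        if self.omega_adia.shape != (n,):
            raise SubspaceError(
                f"omega_adia has shape {self.omega_adia.shape}, expected ({n},)"
            )
        if self.dipoles is not None and self.dipoles.shape != (n, 3):
            raise SubspaceError(
                f"dipoles have shape {self.dipoles.shape}, expected ({n}, 3)"
            )
        if self.diag_elements is not None and self.diag_elements.h_qq.shape != (n, n):
            raise SubspaceError("diag_elements.h_qq dimension mismatch")
        # A - B positive definite is the precondition for the symmetric folding
        amb = 0.5 * (self.a_adia + self.a_adia.T) - 0.5 * (self.b_adia + self.b_adia.T)
        if n:
            lo = float(np.linalg.eigvalsh(amb)[0])
            if lo <= 0:
                raise SubspaceError(
                    f"A_adia - B_adia not positive definite (lowest eigenvalue {lo:.3e})"
                )


def build_subspace(
    orbitals: OrbitalSpectrum,
    single_specs: Sequence[Tuple[int, int]],
    double_spec: Tuple[int, int],
    a_adia: np.ndarray,
    b_adia: np.ndarray,
    h_qd: np.ndarray,
    omega_adia: np.ndarray,
    omega_adia_s1: Optional[float] = None,
    omega_adia_s2: Optional[float] = None,
    dipoles: Optional[np.ndarray] = None,
    diag_elements: Optional[DiagonalElements] = None,
    sym_tol: float = 1e-7,
) -> TruncatedSubspace:
    """Assemble and validate a :class:`TruncatedSubspace`.

    KS frequencies are computed from ``orbitals``; the singles keep the
    caller's order.  ``omega_adia_s1/s2`` default to the ATDDFT frequency of
    the double's constituent single if that single appears in
    ``single_specs``, otherwise they must be given.
    """
    singles = tuple(
        SingleExcitation(occ, vir, orbitals.nu(occ, vir)) for occ, vir in single_specs
    )
    p, r = double_spec
    constituent = SingleExcitation(p, r, orbitals.nu(p, r))
    double = DoubleExcitation(p, r, constituent, constituent, 2.0 * constituent.nu_q)

    if omega_adia_s1 is None or omega_adia_s2 is None:
        pairs = [(s.occ, s.vir) for s in singles]
        if (p, r) in pairs:
            fallback = float(np.asarray(omega_adia)[pairs.index((p, r))])
            omega_adia_s1 = fallback if omega_adia_s1 is None else omega_adia_s1
            omega_adia_s2 = fallback if omega_adia_s2 is None else omega_adia_s2
        else:
            raise SubspaceError(
                "omega_adia_s1/s2 must be supplied when the double's constituent "
                "single is not part of the subspace"
            )

    subspace = TruncatedSubspace(
        singles=singles,
        double=double,
        a_adia=a_adia,
        b_adia=b_adia,
        h_qd=h_qd,
        omega_adia=omega_adia,
        omega_adia_s1=float(omega_adia_s1),
        omega_adia_s2=float(omega_adia_s2),
        dipoles=dipoles,
        diag_elements=diag_elements,
    )
    subspace.validate(sym_tol=sym_tol)
    return subspace


class NoDoubleFoundError(LookupError):
    """No candidate double excitation lies within the requested window."""


def select_double(
    orbitals: OrbitalSpectrum,
    singles: Sequence[SingleExcitation],
    window: float = 0.5,
) -> DoubleExcitation:
    """Pick the same-orbital-pair double whose KS frequency is closest to the
    mean of the singles' KS frequencies.

    Only candidates with ``|nu_D - mean(nu_q)| <= window`` qualify; ties are
    broken by lexicographic ``(occ_pair, vir_pair)`` order.  Raises
    :class:`NoDoubleFoundError` if nothing qualifies — never a silent
    fallback.
    """
    if not singles:
        raise SubspaceError("need at least one single excitation")
    target = float(np.mean([s.nu_q for s in singles]))
    best = None
    for p in range(orbitals.n_occupied):
        for r in range(orbitals.n_occupied, orbitals.n_orbitals):
            nu_d = 2.0 * orbitals.nu(p, r)
            dist = abs(nu_d - target)
            if dist > window:
                continue
            key = (dist, p, r)
            if best is None or key < best[0]:
                best = (key, p, r)
    if best is None:
        raise NoDoubleFoundError(
            f"no same-pair double within {window} hartree of the singles' "
            f"mean KS frequency {target:.6f}"
        )
    _, p, r = best
    s = SingleExcitation(p, r, orbitals.nu(p, r))
    return DoubleExcitation(p, r, s, s, 2.0 * s.nu_q)
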