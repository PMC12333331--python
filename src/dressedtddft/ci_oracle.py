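"""Brute-force configuration-interaction references.

Everything here exists to validate the production modules: diagonalization
of the squared shifted Hamiltonian in the truncated configuration space,
the scalar effective-frequency map it resolves to, and a dense full CI on
tiny (<= 4 spatial orbital) models built by direct second-quantized
operator action — deliberately independent of the Slater-Condon code path
it is used to check.  None of this ships in the production pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Tuple

import numpy as np

from .matrix_elements import MOIntegrals

__all__ = [
    "ModelHamiltonian",
    "squared_spectrum",
    "effective_frequency",
    "full_ci_small",
    "determinant_basis",
]

MAX_ORBITALS = 4


class OracleError(ValueError):
    pass


@dataclass(frozen=True)
class ModelHamiltonian:
    """Symmetric Hamiltonian over configurations (singles..., double).

    The last basis index is the double excitation; ``c_q`` optionally holds
    the normalized mixing coefficients of the singles for the multi-single
    effective-frequency map.
    """

    h: np.ndarray
    e0: float
    c_q: Optional[np.ndarray] = None

    def __post_init__(self):
        h = np.asarray(self.h, dtype=float)
        object.__setattr__(self, "h", h)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise OracleError("H must be square")
        if np.max(np.abs(h - h.T)) > 1e-12:
            raise OracleError("H must be symmetric")
        if self.c_q is not None:
            object.__setattr__(self, "c_q", np.asarray(self.c_q, dtype=float))

    @property
    def dimension(self) -> int:
        return self.h.shape[0]

    @property
    def n_singles(self) -> int:
        return self.dimension - 1


def squared_spectrum(model: ModelHamiltonian) -> np.ndarray:
    """Positive square roots of the eigenvalues of (H - E0)^2, ascending."""
    shifted = model.h - model.e0 * np.eye(model.dimension)
    vals = np.linalg.eigvalsh(shifted @ shifted)
    return np.sqrt(np.clip(vals, 0.0, None))


def effective_frequency(model: ModelHamiltonian, omega_trial: float,
                        c_q: Optional[np.ndarray] = None) -> float:
    """The squared-frequency map whose fixed points are exact eigenvalues.

    omega^2 = (H_QQ - E0)^2
              + |H_QD|^2 [1 + (H_QQ + H_DD - 2 E0)^2
                              / (omega_trial^2 - ((H_DD - E0)^2 + |H_QD|^2))]

    with H_QQ = c* c H_qq' and H_QD = sum_q c_q* H_qD in the multi-single
    case.  The last denominator term (the coupling) is kept here; only the
    production kernels drop it.
    """
    c = c_q if c_q is not None else model.c_q
    n = model.n_singles
    if n == 1:
        h_qq = model.h[0, 0]
        h_qd2 = model.h[0, 1] ** 2
    else:
        if c is None:
            raise OracleError("multi-single effective frequency needs c_q")
        c = np.asarray(c, dtype=float)
        c = c / np.linalg.norm(c)
        h_qq = float(c @ model.h[:n, :n] @ c)
        h_qd2 = float((c @ model.h[:n, n]) ** 2)
    h_dd = model.h[n, n]
    e0 = model.e0
    pole = (h_dd - e0) ** 2 + h_qd2
    denom = omega_trial**2 - pole
    if denom == 0:
        raise OracleError("effective frequency evaluated at the pole")
    return (h_qq - e0) ** 2 + h_qd2 * (
        1.0 + (h_qq + h_dd - 2.0 * e0) ** 2 / denom
    )


# ---------------------------------------------------------------------------
# Dense full CI by second-quantized operator action on bitstring kets.
# ---------------------------------------------------------------------------


def determinant_basis(n_orbitals: int, n_electrons: int) -> List[Tuple[int, ...]]:
    """All spin-orbital determinants (sorted tuples, 2p+sigma encoding)."""
    return list(combinations(range(2 * n_orbitals), n_electrons))


def _apply_ops(det: Tuple[int, ...], annihilate: Tuple[int, ...],
               create: Tuple[int, ...]):
    """Apply ... a^dag_{c1} a^dag_{c0} ... a_{a0} a_{a1} right-to-left."""
    occ = list(det)
    sign = 1
    for a in annihilate:
        if a not in occ:
            return None
        i = occ.index(a)
        sign *= (-1) ** i
        del occ[i]
    for c in create:
        if c in occ:
            return None
        j = 0
        while j < len(occ) and occ[j] < c:
            j += 1
        sign *= (-1) ** j
        occ.insert(j, c)
    return tuple(occ), sign


def full_ci_small(integrals: MOIntegrals, n_electrons: int):
    """Dense determinant-basis Hamiltonian and its spectrum.

    H = E_core + sum h_pq a+_p a_q + 1/2 sum (pq|rs) a+_p a+_r a_s a_q
    (chemist-notation spatial integrals, summed over spins).  Capped at
    four spatial orbitals.

    Returns ``(basis, H, eigenvalues)``.
    """
    n = integrals.n_orbitals
    if n > MAX_ORBITALS:
        raise OracleError(f"full CI oracle capped at {MAX_ORBITALS} orbitals, got {n}")
    basis = determinant_basis(n, n_electrons)
    index = {det: k for k, det in enumerate(basis)}
    dim = len(basis)
    h = np.zeros((dim, dim))
    h1 = integrals.one_electron
    eri = integrals.two_electron
    core = integrals.core_energy or 0.0
    for k, det in enumerate(basis):
        h[k, k] += core
        for p in range(n):
            for q in range(n):
                hval = h1[p, q] if h1 is not None else 0.0
                for sigma in (0, 1):
                    if hval != 0.0:
                        res = _apply_ops(det, (2 * q + sigma,), (2 * p + sigma,))
                        if res is not None:
                            new, sign = res
                            h[index[new], k] += sign * hval
                for r in range(n):
                    for s in range(n):
                        v = eri[p, q, r, s]
                        if v == 0.0:
                            continue
                        for sigma in (0, 1):
                            for tau in (0, 1):
                                # 1/2 (pq|rs) a+_{p sigma} a+_{r tau} a_{s tau} a_{q sigma}
                                res = _apply_ops(
                                    det,
                                    (2 * q + sigma, 2 * s + tau),
                                    (2 * r + tau, 2 * p + sigma),
                                )
                                if res is not None:
                                    new, sign = res
                                    h[index[new], k] += 0.5 * sign * v
    vals = np.linalg.eigvalsh(0.5 * (h + h.T))
    return basis, h, vals
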