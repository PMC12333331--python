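"""Frequency-dependent dressing matrices X(omega).

Three variants of the additive kernel correction are provided.  Writing
``P_qq' = H_qD H_Dq' / (4 sqrt(nu_q nu_q'))``:

* ``S``:    X = P * [1 + (nu_q + nu_D)(nu_q' + nu_D) / (omega^2 - nu_D^2)]
* ``a``:    as S, with the numerator shifts and the pole position taken
            from ATDDFT frequencies: (Omega_q^A + Omega_s1^A + Omega_s2^A)
            and (Omega_s1^A + Omega_s2^A)^2.  The 1/(4 sqrt(nu_q nu_q'))
            prefactor keeps the bare KS frequencies, as the variant is
            defined (one might expect ATDDFT values there too; it is
            implemented as defined).
* ``zero``: X = P * [1 + (H_qq' + H_DD - 2 H_00)^2 / (omega^2 - (H_DD - H_00)^2)],
            requiring the optional diagonal Hamiltonian elements.

All variants drop the coupling term from the pole denominator of the exact
configuration-space resolution; this keeps the kernel invariant under the
arbitrary sign of each KS state and makes the Tamm-Dancoff limit reduce to
the dressed-TDA construction.  The scalar SMA kernel (:func:`dsma_kernel`)
retains that term for its 0-variant, matching the exact two-level
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .excitation_space import TruncatedSubspace

__all__ = [
    "DressingSpec",
    "DressingMatrix",
    "dressing_S",
    "dressing_a",
    "dressing_zero",
    "dressing_none",
    "evaluate_dressing",
    "dressing_pole_omega2",
    "dsma_kernel",
]

VARIANTS = ("S", "a", "zero", "none")


class DressingError(ValueError):
    pass


class PoleEvaluationError(DressingError):
    """Kernel evaluated at (or within pole_shift of) its pole."""


@dataclass(frozen=True)
class DressingSpec:
    """Which dressing to apply and in which response framework.

    ``pole_shift`` is a small real guard distance (hartree^2 on the
    omega^2 axis): evaluation closer to the pole raises, and the
    self-consistent solver bisects instead of stepping into the guard.
    """

    variant: str = "a"
    tamm_dancoff: bool = False
    pole_shift: float = 0.0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise DressingError(
                f"unknown dressing variant {self.variant!r}; choose from {VARIANTS}"
            )
        if self.pole_shift < 0:
            raise DressingError("pole_shift must be non-negative")


@dataclass(frozen=True)
class DressingMatrix:
    """The additive kernel correction evaluated at one frequency.

    ``dx_domega2`` is the closed-form derivative of X with respect to
    omega^2, needed for the eigenvector normalization.
    """

    x: np.ndarray
    omega: float
    dx_domega2: np.ndarray


def _prefactor(subspace: TruncatedSubspace) -> np.ndarray:
    nu = subspace.nu
    h = subspace.h_qd
    return np.outer(h, h) / (4.0 * np.sqrt(np.outer(nu, nu)))


def _check_pole(omega: float, pole_omega2: float, pole_shift: float) -> None:
    if abs(omega * omega - pole_omega2) <= max(pole_shift, 1e-300):
        raise PoleEvaluationError(
            f"dressing evaluated at omega={omega:.8f} within {pole_shift} of the "
            f"pole at omega^2={pole_omega2:.8f}; use a pole_shift guard or step away"
        )


def _rank_one(subspace, omega, shifts, pole_omega2, pole_shift) -> DressingMatrix:
    """Common form P * [1 + outer(shifts, shifts) / (omega^2 - pole)]."""
    _check_pole(omega, pole_omega2, pole_shift)
    pref = _prefactor(subspace)
    numer = np.outer(shifts, shifts)
    denom = omega * omega - pole_omega2
    x = pref * (1.0 + numer / denom)
    dx = -pref * numer / denom**2
    return DressingMatrix(x=x, omega=float(omega), dx_domega2=dx)


def dressing_S(subspace: TruncatedSubspace, omega: float,
               pole_shift: float = 0.0) -> DressingMatrix:
    """S-variant: shifts and pole from bare KS frequencies."""
    shifts = subspace.nu + subspace.nu_d
    return _rank_one(subspace, omega, shifts, subspace.nu_d**2, pole_shift)


def dressing_a(subspace: TruncatedSubspace, omega: float,
               pole_shift: float = 0.0) -> DressingMatrix:
    """a-variant: shifts and pole from ATDDFT frequencies."""
    omega_s12 = subspace.omega_adia_s1 + subspace.omega_adia_s2
    shifts = subspace.omega_adia + omega_s12
    return _rank_one(subspace, omega, shifts, omega_s12**2, pole_shift)


def dressing_zero(subspace: TruncatedSubspace, omega: float,
                  pole_shift: float = 0.0) -> DressingMatrix:
    """0-variant: shifts and pole from diagonal Hamiltonian elements.

    The numerator carries the (q, q')-dependent H_qq', so this variant is
    not rank-one in general.
    """
    diag = subspace.diag_elements
    if diag is None:
        raise DressingError(
            "0-variant requires diag_elements (H_qq', H_DD, H_00) on the subspace"
        )
    pole_omega2 = (diag.h_dd - diag.h_00) ** 2
    _check_pole(omega, pole_omega2, pole_shift)
    pref = _prefactor(subspace)
    numer = (diag.h_qq + diag.h_dd - 2.0 * diag.h_00) ** 2
    denom = omega * omega - pole_omega2
    x = pref * (1.0 + numer / denom)
    dx = -pref * numer / denom**2
    return DressingMatrix(x=x, omega=float(omega), dx_domega2=dx)


def dressing_none(subspace: TruncatedSubspace, omega: float) -> DressingMatrix:
    n = subspace.n_singles
    z = np.zeros((n, n))
    return DressingMatrix(x=z, omega=float(omega), dx_domega2=z.copy())


def evaluate_dressing(subspace: TruncatedSubspace, spec: DressingSpec,
                      omega: float) -> DressingMatrix:
    """Dispatch on ``spec.variant``."""
    if spec.variant == "none":
        return dressing_none(subspace, omega)
    if spec.variant == "S":
        return dressing_S(subspace, omega, spec.pole_shift)
    if spec.variant == "a":
        return dressing_a(subspace, omega, spec.pole_shift)
    return dressing_zero(subspace, omega, spec.pole_shift)


def dressing_pole_omega2(subspace: TruncatedSubspace,
                         spec: DressingSpec) -> Optional[float]:
    """Squared-frequency position of the kernel pole, or None for 'none'."""
    if spec.variant == "none":
        return None
    if spec.variant == "S":
        return float(subspace.nu_d**2)
    if spec.variant == "a":
        return float((subspace.omega_adia_s1 + subspace.omega_adia_s2) ** 2)
    diag = subspace.diag_elements
    if diag is None:
        raise DressingError("0-variant requires diag_elements")
    return float((diag.h_dd - diag.h_00) ** 2)


def _dsma_terms(subspace: TruncatedSubspace, variant: str):
    """(shift^2 numerator, pole in omega^2) for the scalar SMA kernel."""
    nu_q = subspace.nu[0]
    h_qd = subspace.h_qd[0]
    if variant == "S":
        return (nu_q + subspace.nu_d) ** 2, subspace.nu_d**2
    if variant == "a":
        omega_s12 = subspace.omega_adia_s1 + subspace.omega_adia_s2
        return (subspace.omega_adia[0] + omega_s12) ** 2, omega_s12**2
    if variant == "zero":
        diag = subspace.diag_elements
        if diag is None:
            raise DressingError("0-variant requires diag_elements")
        h_qq = diag.h_qq[0, 0]
        numer = (h_qq + diag.h_dd - 2.0 * diag.h_00) ** 2
        # the exact two-level resolution keeps the coupling in the pole
        pole = (diag.h_dd - diag.h_00) ** 2 + h_qd**2
        return numer, pole
    raise DressingError(f"dsma_kernel does not accept variant {variant!r}")


def dsma_kernel(subspace: TruncatedSubspace, variant: str, omega: float,
                pole_shift: float = 0.0) -> float:
    """Scalar dressed-SMA kernel correction for a one-single subspace.

    For variants S and a this equals the 1x1 matrix dressing (the 4 nu_q
    and 4 sqrt(nu_q nu_q') prefactors coincide).  The 0-variant keeps the
    coupling |H_QD|^2 inside the pole denominator, matching the exact
    two-level configuration resolution; the matrix 0-variant drops it.
    """
    if subspace.n_singles != 1:
        raise DressingError(
            f"dsma_kernel requires exactly one single excitation, got "
            f"{subspace.n_singles}"
        )
    numer, pole = _dsma_terms(subspace, variant)
    _check_pole(omega, pole, pole_shift)
    nu_q = subspace.nu[0]
    pref = subspace.h_qd[0] ** 2 / (4.0 * nu_q)
    return float(pref * (1.0 + numer / (omega * omega - pole)))


def dsma_kernel_derivative(subspace: TruncatedSubspace, variant: str,
                           omega: float, pole_shift: float = 0.0) -> float:
    """d(dsma_kernel)/d(omega^2), closed form."""
    numer, pole = _dsma_terms(subspace, variant)
    _check_pole(omega, pole, pole_shift)
    nu_q = subspace.nu[0]
    pref = subspace.h_qd[0] ** 2 / (4.0 * nu_q)
    return float(-pref * numer / (omega * omega - pole) ** 2)
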