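"""Self-consistent solution of the dressed response problem.

The dressed matrices are ``A = A_adia + 2 X(omega)`` and
``B = B_adia + 2 X(omega)`` (factor 2 mirroring the singlet convention
``A = delta nu + 2 f_HXC``); folding with
``Omega = (A-B)^{1/2} (A+B) (A-B)^{1/2}`` then reproduces the
``nu^2 delta + 4 sqrt(nu nu') (f + X)`` response matrix whenever the
adiabatic blocks carry that structure.  Because the same correction enters
A and B, ``A - B`` is frequency independent in the full-response case.

The pseudoeigenvalue problem is solved by fixed-point iteration from the
adiabatic frequency of the targeted state, following the root across
iterations by maximal eigenvector overlap, with a damped update on
period-2 cycling and bisection away from the kernel pole.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .dressing import (
    DressingSpec,
    dressing_pole_omega2,
    dsma_kernel,
    dsma_kernel_derivative,
    evaluate_dressing,
)
from .excitation_space import TruncatedSubspace
from .units import HARTREE_TO_MEV

logger = logging.getLogger(__name__)

__all__ = [
    "ResponseMatrices",
    "ExcitedState",
    "SolverError",
    "build_dressed",
    "casida_fold",
    "solve_state",
    "solve_all_states",
    "solve_dsma",
    "normalize_state",
    "oscillator_strength",
]


class SolverError(RuntimeError):
    pass


class InstabilityError(SolverError):
    """A - B is not positive definite; the folded problem is undefined."""


@dataclass(frozen=True)
class ResponseMatrices:
    """Dressed (or adiabatic) response blocks evaluated at one frequency."""

    a: np.ndarray
    b: np.ndarray
    omega: float


@dataclass
class ExcitedState:
    """A converged (or flagged) solution of the dressed response problem."""

    omega: float
    g: np.ndarray
    norm_weight: float
    iterations: int
    converged: bool
    oscillator_strength: Optional[float] = None
    label: Optional[str] = None
    history: List[float] = field(default_factory=list)

    @property
    def omega_ev(self) -> float:
        from .units import HARTREE_TO_EV

        return self.omega * HARTREE_TO_EV


def build_dressed(subspace: TruncatedSubspace, spec: DressingSpec,
                  omega: float) -> ResponseMatrices:
    """Add the dressing to the adiabatic blocks; honor the Tamm-Dancoff flag."""
    dm = evaluate_dressing(subspace, spec, omega)
    a = subspace.a_adia + 2.0 * dm.x
    if spec.tamm_dancoff:
        b = np.zeros_like(a)
    else:
        b = subspace.b_adia + 2.0 * dm.x
    return ResponseMatrices(a=a, b=b, omega=float(omega))


def _sqrtm_pd(m: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (m + m.T))
    if vals[0] < floor:
        raise InstabilityError(
            f"A - B not positive definite: lowest eigenvalue {vals[0]:.3e} "
            f"below floor {floor:.0e}"
        )
    return (vecs * np.sqrt(vals)) @ vecs.T


def casida_fold(matrices: ResponseMatrices) -> np.ndarray:
    """Symmetric folded matrix (A-B)^{1/2} (A+B) (A-B)^{1/2}.

    Its eigenvalues are the squared frequencies of the (A B; B A)
    pseudoeigenvalue problem for real orbitals.
    """
    s = _sqrtm_pd(matrices.a - matrices.b)
    return s @ (matrices.a + matrices.b) @ s


def _folded_eigh(subspace, spec, omega):
    m = casida_fold(build_dressed(subspace, spec, omega))
    return np.linalg.eigh(0.5 * (m + m.T))


def solve_state(
    subspace: TruncatedSubspace,
    spec: DressingSpec,
    target: int = 0,
    tol: float = 1e-6,
    max_iter: int = 50,
    label: Optional[str] = None,
) -> ExcitedState:
    """Fixed-point solve for one state of the dressed problem.

    ``target`` selects the adiabatic state (index into the ascending
    adiabatic spectrum computed with the same Tamm-Dancoff setting) whose
    frequency seeds the iteration and whose eigenvector seeds the
    overlap-based root following.
    """
    if tol <= 0:
        raise SolverError("tol must be positive")
    adia_spec = DressingSpec(variant="none", tamm_dancoff=spec.tamm_dancoff)
    vals0, vecs0 = _folded_eigh(subspace, adia_spec, 1.0)
    if not 0 <= target < subspace.n_singles:
        raise SolverError(f"target index {target} outside subspace of size "
                          f"{subspace.n_singles}")
    omega = float(np.sqrt(vals0[target]))
    v_prev = vecs0[:, target]

    if spec.variant == "none":
        state = ExcitedState(
            omega=omega, g=v_prev.copy(), norm_weight=1.0, iterations=1,
            converged=True, label=label, history=[omega],
        )
        _attach_normalization(state, subspace, spec)
        return state

    pole = dressing_pole_omega2(subspace, spec)
    history = [omega]
    converged = False
    delta_prev = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        vals, vecs = _folded_eigh(subspace, spec, omega)
        overlaps = np.abs(vecs.T @ v_prev)
        idx = int(np.argmax(overlaps))
        if vals[idx] <= 0:
            raise SolverError(
                f"followed root has non-positive squared frequency {vals[idx]:.3e}"
            )
        omega_new = float(np.sqrt(vals[idx]))
        v_prev = vecs[:, idx]
        delta = omega_new - omega
        if delta_prev is not None and delta * delta_prev < 0 and abs(delta) > 0.5 * abs(delta_prev):
            logger.info("period-2 oscillation detected; damping the update")
            omega_new = 0.5 * (omega_new + omega)
            delta = omega_new - omega
        if pole is not None and spec.pole_shift > 0:
            while abs(omega_new**2 - pole) <= spec.pole_shift and abs(omega_new - omega) > 1e-15:
                omega_new = 0.5 * (omega_new + omega)  # bisect away from the pole
            delta = omega_new - omega
        history.append(omega_new)
        logger.debug(
            "iteration %d: omega = %.10f hartree (delta = %.4f meV)",
            iterations, omega_new, delta * HARTREE_TO_MEV,
        )
        omega, delta_prev = omega_new, delta
        if abs(delta) <= tol:
            converged = True
            break
    if not converged:
        logger.warning("solve_state did not converge in %d iterations", max_iter)
    state = ExcitedState(
        omega=omega, g=v_prev.copy(), norm_weight=1.0, iterations=iterations,
        converged=converged, label=label, history=history,
    )
    _attach_normalization(state, subspace, spec)
    return state


def folded_derivative(subspace: TruncatedSubspace, spec: DressingSpec,
                      omega: float) -> np.ndarray:
    """d(Omega)/d(omega^2) of the folded matrix, closed form.

    Full response: A - B is frequency independent, so the derivative is
    S (4 dX/domega^2) S with S = (A_adia - B_adia)^{1/2}.  Under
    Tamm-Dancoff the folded matrix is A(omega)^2 and the chain rule gives
    2 (X' A + A X').
    """
    dm = evaluate_dressing(subspace, spec, omega)
    if spec.tamm_dancoff:
        a = subspace.a_adia + 2.0 * dm.x
        return 2.0 * (dm.dx_domega2 @ a + a @ dm.dx_domega2)
    s = _sqrtm_pd(subspace.a_adia - subspace.b_adia)
    return 4.0 * (s @ dm.dx_domega2 @ s)


def normalize_state(
    g_raw: np.ndarray,
    subspace: TruncatedSubspace,
    spec: DressingSpec,
    omega: float,
):
    """Scale the eigenvector so G^T (1 - dOmega/domega^2) G = 1.

    Returns ``(g, norm_weight)`` with ``norm_weight = G^T G``, the
    single-excitation fraction of the state (1 exactly when the kernel is
    frequency independent).
    """
    g_raw = np.asarray(g_raw, dtype=float)
    metric = np.eye(subspace.n_singles) - folded_derivative(subspace, spec, omega)
    quad = float(g_raw @ metric @ g_raw)
    if quad <= 0:
        raise SolverError(
            f"non-positive normalization quadratic form ({quad:.3e}); the "
            "converged frequency is pathologically close to the kernel pole"
        )
    g = g_raw / np.sqrt(quad)
    return g, float(g @ g)


def _attach_normalization(state: ExcitedState, subspace, spec) -> None:
    g, weight = normalize_state(state.g, subspace, spec, state.omega)
    state.g = g
    state.norm_weight = weight


def oscillator_strength(
    state: ExcitedState,
    dipoles: Optional[np.ndarray],
    subspace: TruncatedSubspace,
) -> float:
    """Length-gauge oscillator strength from the normalized eigenvector.

    f_I = (2/3) omega_I sum_axes |sum_q d_q sqrt(nu_q / omega_I) G_q|^2.
    The fixed convention satisfies the subspace sum rule: the total over
    all roots of the dressed problem equals the adiabatic total.
    """
    if dipoles is None:
        dipoles = subspace.dipoles
    if dipoles is None:
        raise SolverError("transition dipoles are required for oscillator strengths")
    dipoles = np.asarray(dipoles, dtype=float)
    weights = np.sqrt(subspace.nu / state.omega) * state.g
    t = dipoles.T @ weights  # 3-vector
    return float(2.0 / 3.0 * state.omega * np.dot(t, t))


def solve_all_states(
    subspace: TruncatedSubspace,
    spec: DressingSpec,
    omega_max: Optional[float] = None,
    n_grid: int = 4000,
    tol: float = 1e-12,
) -> List[ExcitedState]:
    """Locate every root of det(Omega(omega) - omega^2) by branch scanning.

    Sorted eigenvalue branches of the folded matrix are scanned on an
    omega grid; each sign change of ``branch(omega) - omega^2`` is refined
    by bisection.  For the rank-one S/a dressings over n singles this
    yields n+1 roots (the extra one carrying the double character).
    """
    pole = dressing_pole_omega2(subspace, spec)
    adia_spec = DressingSpec(variant="none", tamm_dancoff=spec.tamm_dancoff)
    vals0, _ = _folded_eigh(subspace, adia_spec, 1.0)
    top = float(np.sqrt(vals0[-1]))
    if omega_max is None:
        omega_max = 2.0 * top + (np.sqrt(pole) if pole else 0.0)
    grid = np.linspace(1e-4, omega_max, n_grid)
    if pole is not None:
        guard = max(spec.pole_shift, 1e-11)
        # roots can hug the pole; refine both sides logarithmically
        eps = np.geomspace(1e-10, max(0.5, 0.1 * pole), 200)
        extra = np.concatenate([pole + eps, pole - eps[pole - eps > 0]])
        extra = np.sqrt(extra[extra > 0])
        grid = np.unique(np.concatenate([grid, extra]))
        grid = grid[np.abs(grid**2 - pole) > guard]
    n = subspace.n_singles

    def branches(w):
        vals, _ = _folded_eigh(subspace, spec, w)
        return vals

    prev = branches(grid[0]) - grid[0] ** 2
    roots: List[float] = []
    for k in range(1, grid.size):
        w = grid[k]
        if pole is not None and np.sign(grid[k - 1] ** 2 - pole) != np.sign(w**2 - pole):
            prev = branches(w) - w**2
            continue  # never bracket across the pole
        cur = branches(w) - w**2
        for i in range(n):
            if prev[i] == 0.0 or np.sign(prev[i]) == np.sign(cur[i]):
                continue
            lo, hi = grid[k - 1], w
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                fm = branches(mid)[i] - mid**2
                if hi - lo < tol:
                    break
                if np.sign(fm) == np.sign(prev[i]):
                    lo = mid
                else:
                    hi = mid
            roots.append(0.5 * (lo + hi))
        prev = cur
    states = []
    for root in sorted(roots):
        vals, vecs = _folded_eigh(subspace, spec, root)
        idx = int(np.argmin(np.abs(vals - root**2)))
        state = ExcitedState(
            omega=float(root), g=vecs[:, idx], norm_weight=1.0,
            iterations=0, converged=True,
        )
        _attach_normalization(state, subspace, spec)
        states.append(state)
    return states


def solve_dsma(
    subspace: TruncatedSubspace,
    variant: str,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> ExcitedState:
    """Self-consistent dressed-SMA frequency for a one-single subspace.

    Iterates ``omega^2 = nu_q^2 + 4 nu_q (f_adia + X(omega))`` with the
    adiabatic SMA start, falling back to bracketed bisection when the plain
    fixed point cycles.  ``f_adia`` is read off the stored adiabatic blocks
    as ``B_adia/2`` plus any non-diagonal-nu deviation of ``A_adia``.
    """
    if subspace.n_singles != 1:
        raise SolverError("solve_dsma requires a one-single subspace")
    nu = subspace.nu[0]
    # SMA adiabatic omega^2 from the stored 1x1 blocks via folding
    a0 = subspace.a_adia[0, 0]
    b0 = subspace.b_adia[0, 0]
    base = (a0 - b0) * (a0 + b0)  # adiabatic omega^2

    def rhs(w):
        return base + 4.0 * nu * dsma_kernel(subspace, variant, w)

    omega = float(np.sqrt(base))
    history = [omega]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        w2 = rhs(omega)
        if w2 <= 0:
            break
        omega_new = float(np.sqrt(w2))
        history.append(omega_new)
        if abs(omega_new - omega) <= tol:
            omega = omega_new
            converged = True
            break
        if iterations > 20 and len(history) > 3 and (
            abs(history[-1] - history[-3]) < 0.1 * abs(history[-1] - history[-2])
        ):
            break  # cycling: hand over to bisection
        omega = omega_new
    if not converged:
        omega = _dsma_bisect(rhs, history)
        converged = omega is not None
        if omega is None:
            omega = history[-1]
    norm = 1.0
    deriv = 4.0 * nu * dsma_kernel_derivative(subspace, variant, omega) if variant != "none" else 0.0
    quad = 1.0 - deriv
    if quad > 0:
        norm = 1.0 / quad
    return ExcitedState(
        omega=float(omega), g=np.array([1.0 / np.sqrt(quad)]) if quad > 0 else np.array([1.0]),
        norm_weight=norm, iterations=iterations, converged=bool(converged),
        history=history,
    )


def _dsma_bisect(rhs, history):
    """Bracketed bisection on omega^2 - rhs(omega) near the last iterates."""

    def f(w):
        return w * w - rhs(w)

    candidates = sorted(set(history))
    points = np.unique(np.concatenate([
        np.asarray(candidates),
        np.linspace(0.5 * min(candidates), 2.0 * max(candidates), 200),
    ]))
    vals = []
    for w in points:
        try:
            vals.append(f(w))
        except Exception:
            vals.append(np.nan)
    vals = np.asarray(vals)
    for i in range(len(points) - 1):
        if np.isnan(vals[i]) or np.isnan(vals[i + 1]):
            continue
        if np.sign(vals[i]) != np.sign(vals[i + 1]):
            import scipy.optimize

            try:
                return float(scipy.optimize.brentq(f, points[i], points[i + 1],
                                                   xtol=1e-14))
            except Exception:
                continue
    return None
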