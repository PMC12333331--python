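import dataclasses

import numpy as np
import pytest

from conftest import make_structured_subspace, make_tuned_two_level
from dressedtddft.ci_oracle import squared_spectrum
from dressedtddft.dressing import DressingSpec, evaluate_dressing
from dressedtddft.solver import (
    InstabilityError,
    ResponseMatrices,
    SolverError,
    build_dressed,
    casida_fold,
    folded_derivative,
    normalize_state,
    oscillator_strength,
    solve_all_states,
    solve_dsma,
    solve_state,
)


class TestBuildDressed:
    def test_none_leaves_adiabatic_blocks(self, rng):
        sub = make_structured_subspace(rng)
        m = build_dressed(sub, DressingSpec(variant="none"), 1.0)
        np.testing.assert_array_equal(m.a, sub.a_adia)
        np.testing.assert_array_equal(m.b, sub.b_adia)

    def test_tamm_dancoff_forces_b_to_zero(self, rng):
        sub = make_structured_subspace(rng)
        m = build_dressed(sub, DressingSpec(variant="S", tamm_dancoff=True),
                          sub.nu_d + 0.4)
        assert np.all(m.b == 0.0)

    @pytest.mark.parametrize("draw", range(20))
    def test_folding_identity_against_direct_response_matrix(self, draw):
        """Eigenvalues of the folded dressed problem equal those of the
        nu^2 delta + 4 sqrt(nu nu')(f_adia + X) matrix (mandatory identity
        fixing the factor-2 convention)."""
        rng = np.random.default_rng(1000 + draw)
        sub = make_structured_subspace(rng, n_singles=3)
        spec = DressingSpec(variant="S")
        w = sub.nu_d + 0.3 + rng.uniform(0, 1)
        folded = casida_fold(build_dressed(sub, spec, w))
        x = evaluate_dressing(sub, spec, w).x
        f = sub.b_adia / 2.0 + x
        nu = sub.nu
        direct = np.diag(nu**2) + 4.0 * np.sqrt(np.outer(nu, nu)) * f
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(folded)),
            np.sort(np.linalg.eigvalsh(direct)),
            atol=1e-10,
        )


class TestCasidaFold:
    def test_tda_limit_eigenfrequencies_equal_a_eigenvalues(self, rng):
        sub = make_structured_subspace(rng)
        m = ResponseMatrices(a=sub.a_adia, b=np.zeros_like(sub.a_adia), omega=0.0)
        folded = casida_fold(m)
        np.testing.assert_allclose(
            np.sqrt(np.linalg.eigvalsh(folded)),
            np.linalg.eigvalsh(sub.a_adia),
            atol=1e-12,
        )

    def test_noninteracting_diagonal(self):
        m = ResponseMatrices(a=np.diag([0.37]), b=np.zeros((1, 1)), omega=0.0)
        assert np.sqrt(casida_fold(m)[0, 0]) == pytest.approx(0.37)

    @pytest.mark.parametrize("seed", range(10))
    def test_generalized_eigenproblem_oracle(self, seed):
        """Folded eigenvalues match the dense (A B; -B -A) spectrum."""
        rng = np.random.default_rng(seed)
        sub = make_structured_subspace(rng, n_singles=3)
        a, b = sub.a_adia, sub.b_adia
        big = np.block([[a, b], [-b, -a]])
        ev = np.linalg.eigvals(big)
        pos = np.sort(ev.real[ev.real > 0])
        fold = np.sqrt(np.sort(np.linalg.eigvalsh(
            casida_fold(ResponseMatrices(a, b, 0.0)))))
        np.testing.assert_allclose(fold, pos, atol=1e-10)

    def test_instability_error_names_eigenvalue(self):
        a = np.diag([0.2, 0.3])
        b = np.diag([0.25, 0.1])  # A - B has a negative eigenvalue
        with pytest.raises(InstabilityError, match="-5"):
            casida_fold(ResponseMatrices(a, b, 0.0))


class TestSolveState:
    def test_none_variant_converges_in_one_iteration(self, rng):
        sub = make_structured_subspace(rng)
        st = solve_state(sub, DressingSpec(variant="none"), target=0)
        assert st.converged and st.iterations == 1
        assert st.norm_weight == pytest.approx(1.0)
        folded = casida_fold(build_dressed(sub, DressingSpec(variant="none"), 1.0))
        assert st.omega == pytest.approx(np.sqrt(np.linalg.eigvalsh(folded)[0]))

    def test_fixed_point_is_secular_root(self, rng):
        """The converged frequency solves det(Omega(omega) - omega^2 I) = 0,
        verified by a dense scan oracle."""
        sub = make_structured_subspace(rng, n_singles=2)
        spec = DressingSpec(variant="S")
        st = solve_state(sub, spec, target=0, tol=1e-12)
        assert st.converged
        m = casida_fold(build_dressed(sub, spec, st.omega))
        resid = np.linalg.det(m - st.omega**2 * np.eye(2))
        # compare against the smallest determinant magnitude on a dense scan
        grid = np.linspace(0.2 * st.omega, 2.0 * st.omega, 2000)
        dets = []
        for w in grid:
            try:
                mm = casida_fold(build_dressed(sub, spec, w))
                dets.append(abs(np.linalg.det(mm - w**2 * np.eye(2))))
            except Exception:
                dets.append(np.inf)
        assert abs(resid) < np.percentile(np.asarray(dets), 1)
        # and one of the scan's near-zero local minima sits at the fixed point
        dets = np.asarray(dets)
        step = grid[1] - grid[0]
        minima = [
            grid[k] for k in range(1, len(grid) - 1)
            if dets[k] <= dets[k - 1] and dets[k] <= dets[k + 1]
            and dets[k] < np.median(dets) * 1e-3
        ]
        assert min(abs(m - st.omega) for m in minima) < 2 * step

    def test_adiabatic_limit_recovers_atddft(self, rng):
        """H_qD -> 0 continuously recovers adiabatic energies, unit weights
        and adiabatic oscillator strengths."""
        sub = make_structured_subspace(rng, n_singles=3)
        bare = dataclasses.replace(sub, h_qd=np.zeros(3))
        for target in range(3):
            dressed = solve_state(bare, DressingSpec(variant="S"), target=target)
            adia = solve_state(bare, DressingSpec(variant="none"), target=target)
            assert dressed.omega == pytest.approx(adia.omega, abs=1e-12)
            assert dressed.norm_weight == pytest.approx(1.0, abs=1e-12)
            assert oscillator_strength(dressed, None, sub) == pytest.approx(
                oscillator_strength(adia, None, sub), abs=1e-12
            )

    def test_small_coupling_continuity(self, rng):
        sub = make_structured_subspace(rng, n_singles=2)
        omegas = []
        for scale in (1e-3, 1e-5, 0.0):
            s = dataclasses.replace(sub, h_qd=sub.h_qd * scale)
            omegas.append(solve_state(s, DressingSpec(variant="S"), target=0,
                                      tol=1e-12).omega)
        assert abs(omegas[1] - omegas[2]) < abs(omegas[0] - omegas[2])
        assert omegas[1] == pytest.approx(omegas[2], abs=1e-6)

    def test_nonconvergence_flagged_not_raised(self, rng):
        sub = make_structured_subspace(rng, n_singles=2)
        st = solve_state(sub, DressingSpec(variant="S"), target=0, max_iter=1,
                         tol=1e-14)
        assert not st.converged
        assert st.iterations == 1

    def test_invalid_tolerance(self, rng):
        sub = make_structured_subspace(rng)
        with pytest.raises(SolverError):
            solve_state(sub, DressingSpec(variant="S"), tol=0.0)

    def test_invalid_target(self, rng):
        sub = make_structured_subspace(rng)
        with pytest.raises(SolverError):
            solve_state(sub, DressingSpec(variant="S"), target=5)


class TestNormalization:
    def test_frequency_independent_kernel_gives_unit_weight(self, rng):
        sub = make_structured_subspace(rng)
        g, w = normalize_state(np.array([0.3, 0.4]), sub,
                               DressingSpec(variant="none"), 0.8)
        assert w == pytest.approx(1.0)
        assert np.linalg.norm(g) == pytest.approx(1.0)

    def test_derivative_matches_finite_difference_of_folded_matrix(self, rng):
        """Closed-form folded derivative vs central differences, 1e-7."""
        sub = make_structured_subspace(rng, n_singles=3)
        spec = DressingSpec(variant="a")
        w = np.sqrt((sub.omega_adia_s1 + sub.omega_adia_s2) ** 2 + 0.5)
        h = 1e-6
        fp = casida_fold(build_dressed(sub, spec, np.sqrt(w**2 + h)))
        fm = casida_fold(build_dressed(sub, spec, np.sqrt(w**2 - h)))
        fd = (fp - fm) / (2 * h)
        closed = folded_derivative(sub, spec, w)
        np.testing.assert_allclose(closed, fd, rtol=1e-7, atol=1e-12)

    def test_tda_derivative_matches_finite_difference(self, rng):
        sub = make_structured_subspace(rng, n_singles=2)
        spec = DressingSpec(variant="S", tamm_dancoff=True)
        w = sub.nu_d + 0.6
        h = 1e-6
        fp = casida_fold(build_dressed(sub, spec, np.sqrt(w**2 + h)))
        fm = casida_fold(build_dressed(sub, spec, np.sqrt(w**2 - h)))
        fd = (fp - fm) / (2 * h)
        closed = folded_derivative(sub, spec, w)
        np.testing.assert_allclose(closed, fd, rtol=1e-6, atol=1e-12)

    def test_weight_bounded_by_one_above_pole(self, rng):
        sub = make_structured_subspace(rng, n_singles=2)
        spec = DressingSpec(variant="S")
        st = solve_state(sub, spec, target=1, tol=1e-10)
        if st.omega**2 > sub.nu_d**2:
            assert 0.0 < st.norm_weight <= 1.0


class TestOscillatorStrength:
    def test_zero_dipoles_zero_strength(self, rng):
        sub = make_structured_subspace(rng)
        sub = dataclasses.replace(sub, dipoles=np.zeros((2, 3)))
        st = solve_state(sub, DressingSpec(variant="none"), target=0)
        assert oscillator_strength(st, None, sub) == 0.0

    def test_missing_dipoles_raise(self, rng):
        sub = make_structured_subspace(rng, with_dipoles=False)
        st = solve_state(sub, DressingSpec(variant="none"), target=0)
        with pytest.raises(SolverError, match="dipole"):
            oscillator_strength(st, None, sub)

    def test_adiabatic_strengths_match_independent_formula(self, rng):
        """No dressing: per-state strengths agree with a direct dense
        computation from the folded adiabatic eigenproblem."""
        sub = make_structured_subspace(rng, n_singles=3)
        nu = sub.nu
        s_half = np.diag(np.sqrt(nu))
        folded = s_half @ (sub.a_adia + sub.b_adia) @ s_half
        vals, vecs = np.linalg.eigh(folded)
        omegas = np.sqrt(vals)
        for k in range(3):
            t = sub.dipoles.T @ (np.sqrt(nu / omegas[k]) * vecs[:, k])
            f_ref = 2.0 / 3.0 * omegas[k] * float(t @ t)
            st = solve_state(sub, DressingSpec(variant="none"), target=k)
            assert oscillator_strength(st, None, sub) == pytest.approx(f_ref, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_sum_rule_preserved_under_dressing(self, seed):
        """Total oscillator strength over all roots of the dressed problem
        equals the adiabatic total to 1e-8."""
        rng = np.random.default_rng(200 + seed)
        sub = make_structured_subspace(rng, n_singles=3)
        spec = DressingSpec(variant="a")
        dressed = solve_all_states(sub, spec)
        assert len(dressed) == 4  # n_singles + 1 roots for the rank-one pole
        total = sum(oscillator_strength(s, None, sub) for s in dressed)
        adia = [solve_state(sub, DressingSpec(variant="none"), target=k)
                for k in range(3)]
        total_adia = sum(oscillator_strength(s, None, sub) for s in adia)
        assert total == pytest.approx(total_adia, abs=1e-8)


class TestTdaLimit:
    def test_dressed_tda_matches_scalar_dsma_within_tda(self, rng):
        """One single + TDA: the self-consistent folded solve equals the
        scalar omega = A_00 + 2 X(omega) fixed point (the dressed-TDA
        construction)."""
        _, sub = make_tuned_two_level(rng)
        spec = DressingSpec(variant="S", tamm_dancoff=True)
        st = solve_state(sub, spec, target=0, tol=1e-12)
        from dressedtddft.dressing import dsma_kernel

        w = sub.a_adia[0, 0]
        for _ in range(500):
            w_new = sub.a_adia[0, 0] + 2.0 * dsma_kernel(sub, "S", w)
            if abs(w_new - w) < 1e-13:
                break
            w = 0.5 * (w + w_new)
        assert st.omega == pytest.approx(w, abs=1e-9)


class TestDsmaSolve:
    @pytest.mark.parametrize("seed", range(25))
    def test_oracle_equivalence_on_tuned_models(self, seed):
        """Self-consistent DSMA-0 frequency equals an exact eigenroot of the
        two-level squared-Hamiltonian diagonalization to 1e-9 hartree."""
        rng = np.random.default_rng(3000 + seed)
        model, sub = make_tuned_two_level(rng)
        exact = squared_spectrum(model)
        st = solve_dsma(sub, "zero")
        assert st.converged
        assert min(abs(st.omega - e) for e in exact) < 1e-9

    def test_requires_one_single(self, rng):
        sub = make_structured_subspace(rng, n_singles=2)
        with pytest.raises(SolverError):
            solve_dsma(sub, "S")
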