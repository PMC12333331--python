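import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dressedtddft.backends import generate_model
from dressedtddft.ci_oracle import full_ci_small
from dressedtddft.matrix_elements import (
    IntegralError,
    MOIntegrals,
    _double_det,
    _ground_det,
    _single_dets,
    coupling_H_qD,
    chemist_to_physicist,
    diagonal_elements,
    read_fcidump,
    write_fcidump,
)


def random_integrals(rng, n=4, scale=0.1, with_one_electron=True):
    raw = rng.normal(scale=scale, size=(n, n, n, n))
    eri = np.zeros_like(raw)
    for perm in ((0, 1, 2, 3), (1, 0, 2, 3), (0, 1, 3, 2), (1, 0, 3, 2),
                 (2, 3, 0, 1), (3, 2, 0, 1), (2, 3, 1, 0), (3, 2, 1, 0)):
        eri += raw.transpose(perm)
    eri /= 8.0
    h1 = None
    if with_one_electron:
        h1 = rng.normal(scale=0.5, size=(n, n))
        h1 = 0.5 * (h1 + h1.T)
    return MOIntegrals(two_electron=eri, n_orbitals=n, one_electron=h1,
                       core_energy=float(rng.normal()), n_electrons=4)


class TestFcidumpIO:
    def test_roundtrip_identity(self, rng, tmp_path):
        ints = random_integrals(rng)
        path = tmp_path / "ints.fcidump"
        write_fcidump(path, ints)
        back = read_fcidump(path)
        assert back.n_orbitals == 4
        assert back.n_electrons == 4
        np.testing.assert_allclose(back.two_electron, ints.two_electron, atol=1e-14)
        np.testing.assert_allclose(back.one_electron, ints.one_electron, atol=1e-14)
        assert back.core_energy == pytest.approx(ints.core_energy)

    def test_symmetry_closure_from_canonical_entries(self, tmp_path):
        """A file listing only canonical (pq|rs) entries exposes all 8
        permutations with equal values."""
        path = tmp_path / "canon.fcidump"
        with open(path, "w") as fh:
            fh.write("&FCI NORB=3,NELEC=2,MS2=0,\n&END\n")
            fh.write(" 0.5  2 1 3 1\n")  # (21|31) only
        ints = read_fcidump(path)
        v = ints.two_electron
        expected = {(1, 0, 2, 0), (0, 1, 2, 0), (1, 0, 0, 2), (0, 1, 0, 2),
                    (2, 0, 1, 0), (0, 2, 1, 0), (2, 0, 0, 1), (0, 2, 0, 1)}
        for idx in expected:
            assert v[idx] == pytest.approx(0.5)
        assert np.count_nonzero(v) == len(expected)
        assert ints.symmetry_violation() == 0.0

    def test_index_beyond_norb_rejected(self, tmp_path):
        path = tmp_path / "bad.fcidump"
        with open(path, "w") as fh:
            fh.write("&FCI NORB=4,NELEC=4,MS2=0,\n&END\n")
            fh.write(" 1.0  5 1 1 1\n")
        with pytest.raises(IntegralError, match="outside NORB"):
            read_fcidump(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "nohdr.fcidump"
        path.write_text("1.0 1 1 1 1\n")
        with pytest.raises(IntegralError, match="&FCI"):
            read_fcidump(path)

    def test_lenient_header_whitespace(self, tmp_path):
        path = tmp_path / "nwchem.fcidump"
        path.write_text("&FCI\n NORB = 2,\n NELEC= 2 , MS2=0,\n/\n 0.25 1 1 1 1\n")
        ints = read_fcidump(path)
        assert ints.n_orbitals == 2
        assert ints.two_electron[0, 0, 0, 0] == pytest.approx(0.25)

    def test_conflicting_duplicates_rejected(self, tmp_path):
        path = tmp_path / "dup.fcidump"
        path.write_text(
            "&FCI NORB=2,NELEC=2,MS2=0,\n&END\n 0.5 1 2 1 1\n 0.6 2 1 1 1\n"
        )
        with pytest.raises(IntegralError, match="conflicting"):
            read_fcidump(path)

    @settings(max_examples=30, deadline=None)
    @given(
        entries=st.lists(
            st.tuples(
                st.integers(1, 4), st.integers(1, 4),
                st.integers(1, 4), st.integers(1, 4),
                st.floats(-2.0, 2.0, allow_nan=False, width=32),
            ),
            min_size=1, max_size=8,
        )
    )
    def test_any_entry_set_closes_to_eightfold_symmetry(self, tmp_path_factory,
                                                        entries):
        """Whatever (possibly redundant) entries a file lists, the parsed
        store satisfies the full permutational symmetry."""
        # drop entries that collide on a permutation orbit with a different value
        canon = {}
        ok = []
        for p, q, r, s, v in entries:
            key = min(
                (p, q, r, s), (q, p, r, s), (p, q, s, r), (q, p, s, r),
                (r, s, p, q), (s, r, p, q), (r, s, q, p), (s, r, q, p),
            )
            if key in canon and canon[key] != v:
                continue
            canon[key] = v
            ok.append((p, q, r, s, v))
        path = tmp_path_factory.mktemp("fcid") / "h.fcidump"
        with open(path, "w") as fh:
            fh.write("&FCI NORB=4,NELEC=4,MS2=0,\n&END\n")
            for p, q, r, s, v in ok:
                fh.write(f" {v!r} {p} {q} {r} {s}\n")
        ints = read_fcidump(path)
        assert ints.symmetry_violation() == 0.0

    def test_chemist_to_physicist_transpose(self, rng):
        ints = random_integrals(rng)
        phys = chemist_to_physicist(ints.two_electron)
        # <pr|qs> == (pq|rs)
        assert phys[0, 2, 1, 3] == pytest.approx(ints.two_electron[0, 1, 2, 3])


def _csf_vector(basis_index, q, n_occ, dim):
    vec = np.zeros(dim)
    for res in _single_dets(q, n_occ):
        det, ph = res
        vec[basis_index[det]] += ph / np.sqrt(2.0)
    return vec


class TestCouplingAgainstFullCI:
    """coupling_H_qD and diagonal_elements must agree with dense
    determinant-basis Hamiltonian elements to 1e-10 hartree."""

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_agreement(self, seed):
        bundle = generate_model(seed=seed, n_singles=3, integral_scale=0.15)
        ints = bundle.integrals
        n_occ = bundle.orbitals.n_occupied
        basis, h_dense, _ = full_ci_small(ints, n_electrons=2 * n_occ)
        index = {d: k for k, d in enumerate(basis)}
        dim = len(basis)
        det_d, ph_d = _double_det(bundle.subspace.double, n_occ)
        vec_d = np.zeros(dim)
        vec_d[index[det_d]] = ph_d
        for k, q in enumerate(bundle.subspace.singles):
            vec_q = _csf_vector(index, q, n_occ, dim)
            oracle = vec_q @ h_dense @ vec_d
            mine = coupling_H_qD(ints, q, bundle.subspace.double, n_occupied=n_occ)
            assert mine == pytest.approx(oracle, abs=1e-10)
            assert mine == pytest.approx(bundle.subspace.h_qd[k], abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_diagonal_elements_oracle(self, seed):
        bundle = generate_model(seed=seed, n_singles=2, integral_scale=0.15)
        ints = bundle.integrals
        n_occ = bundle.orbitals.n_occupied
        basis, h_dense, _ = full_ci_small(ints, n_electrons=2 * n_occ)
        index = {d: k for k, d in enumerate(basis)}
        dim = len(basis)
        h_qq, h_dd, h_00 = diagonal_elements(ints, bundle.subspace, n_occ)
        ground = _ground_det(n_occ)
        assert h_00 == pytest.approx(h_dense[index[ground], index[ground]], abs=1e-10)
        det_d, ph_d = _double_det(bundle.subspace.double, n_occ)
        assert h_dd == pytest.approx(h_dense[index[det_d], index[det_d]], abs=1e-10)
        for i, qi in enumerate(bundle.subspace.singles):
            vi = _csf_vector(index, qi, n_occ, dim)
            for j, qj in enumerate(bundle.subspace.singles):
                vj = _csf_vector(index, qj, n_occ, dim)
                assert h_qq[i, j] == pytest.approx(vi @ h_dense @ vj, abs=1e-10)


class TestLimitsAndInvariances:
    def test_zero_integrals_give_zero_coupling(self):
        bundle = generate_model(seed=2, n_singles=2)
        zero = MOIntegrals(two_electron=np.zeros((4, 4, 4, 4)), n_orbitals=4)
        for q in bundle.subspace.singles:
            assert coupling_H_qD(zero, q, bundle.subspace.double) == 0.0

    def test_noninteracting_diagonal_limits(self):
        """With zero two-electron integrals, H_qq - H_00 = nu_q and
        H_DD - H_00 = nu_D exactly."""
        bundle = generate_model(seed=4, n_singles=2)
        ints = MOIntegrals(
            two_electron=np.zeros((4, 4, 4, 4)), n_orbitals=4,
            one_electron=np.diag(bundle.orbitals.orbital_energies),
            core_energy=0.0,
        )
        h_qq, h_dd, h_00 = diagonal_elements(ints, bundle.subspace,
                                             bundle.orbitals.n_occupied)
        for k, q in enumerate(bundle.subspace.singles):
            assert h_qq[k, k] - h_00 == pytest.approx(q.nu_q, abs=1e-12)
        assert h_dd - h_00 == pytest.approx(bundle.subspace.nu_d, abs=1e-12)

    def test_missing_one_electron_data_raises(self):
        bundle = generate_model(seed=3, n_singles=2)
        bare = MOIntegrals(two_electron=bundle.integrals.two_electron, n_orbitals=4)
        with pytest.raises(IntegralError, match="0-variant unavailable"):
            diagonal_elements(bare, bundle.subspace, 2)

    def test_orbital_count_mismatch_raises(self):
        bundle = generate_model(seed=3, n_singles=2)
        small = MOIntegrals(two_electron=np.zeros((2, 2, 2, 2)), n_orbitals=2)
        q = bundle.subspace.singles[0]
        with pytest.raises(IntegralError):
            coupling_H_qD(small, q, bundle.subspace.double, n_occupied=2)

    def test_phase_covariance(self, rng):
        """Flipping the sign of orbital `vir` of q flips H_qD; the dressing
        product H_qD * H_Dq' with the flip applied consistently is unchanged."""
        bundle = generate_model(seed=7, n_singles=2, integral_scale=0.2)
        ints = bundle.integrals
        q0, q1 = bundle.subspace.singles
        d = bundle.subspace.double
        flip_orb = q0.vir
        assert flip_orb not in (d.occ_pair, d.vir_pair)
        eri = ints.two_electron.copy()
        for axis in range(4):
            sl = [slice(None)] * 4
            sl[axis] = flip_orb
            eri[tuple(sl)] *= -1.0
        flipped = MOIntegrals(two_electron=eri, n_orbitals=4)
        h0 = coupling_H_qD(ints, q0, d, n_occupied=2)
        h1 = coupling_H_qD(ints, q1, d, n_occupied=2)
        h0f = coupling_H_qD(flipped, q0, d, n_occupied=2)
        h1f = coupling_H_qD(flipped, q1, d, n_occupied=2)
        assert h0f == pytest.approx(-h0, abs=1e-12)
        assert h1f == pytest.approx(h1, abs=1e-12)  # q1 does not involve flip_orb
        # observable products: (q0,q0) and (q1,q1) diagonal unchanged; the
        # (q0,q1) product flips with the q0 eigenvector component, which is
        # itself sign-flipped, leaving downstream X G G' contributions intact
        assert h0f * h0f == pytest.approx(h0 * h0, abs=1e-14)
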