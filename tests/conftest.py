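import numpy as np
import pytest

from dressedtddft.excitation_space import (
    DiagonalElements,
    OrbitalSpectrum,
    build_subspace,
)


def make_structured_subspace(rng, n_singles=2, coupling_scale=0.05,
                             kernel_scale=0.02, with_dipoles=True,
                             with_diag=False):
    """Random subspace with the A = diag(nu) + 2f, B = 2f response structure
    (A - B positive definite by construction), couplings drawn directly.

    Unlike the synthetic backend this does not tie H_qD to integrals; it is
    the cheap workhorse for solver/dressing tests.
    """
    n_occ = max(1, n_singles)
    energies = np.concatenate([
        np.sort(rng.uniform(-1.2, -0.4, size=n_occ)),
        np.sort(rng.uniform(0.1, 0.9, size=n_singles + 1)),
    ])
    orbitals = OrbitalSpectrum(energies, n_occ)
    pairs = [(i % n_occ, n_occ + i % (n_singles + 1)) for i in range(n_singles)]
    # make pairs unique
    pairs = []
    k = 0
    for i in range(n_occ):
        for a in range(n_occ, len(energies)):
            if k < n_singles:
                pairs.append((i, a))
                k += 1
    nu = np.array([orbitals.nu(i, a) for i, a in pairs])
    f = rng.normal(scale=kernel_scale, size=(n_singles, n_singles))
    f = 0.5 * (f + f.T)
    a_adia = np.diag(nu) + 2.0 * f
    b_adia = 2.0 * f
    h_qd = rng.normal(scale=coupling_scale, size=n_singles)
    omega_adia = nu * rng.uniform(0.9, 1.1, size=n_singles)
    omega_s = float(rng.uniform(0.8, 1.2))
    dipoles = rng.normal(size=(n_singles, 3)) if with_dipoles else None
    diag = None
    if with_diag:
        h_qq = np.diag(nu) + rng.normal(scale=0.01, size=(n_singles, n_singles))
        h_qq = 0.5 * (h_qq + h_qq.T)
        diag = DiagonalElements(h_qq=h_qq, h_dd=float(2 * omega_s),
                                h_00=float(rng.normal(scale=0.05)))
    double_pair = (0, n_occ)  # always a valid occ/vir pair
    return build_subspace(
        orbitals, pairs, double_pair,
        a_adia=a_adia, b_adia=b_adia, h_qd=h_qd, omega_adia=omega_adia,
        omega_adia_s1=omega_s, omega_adia_s2=omega_s,
        dipoles=dipoles, diag_elements=diag,
    )


def make_tuned_two_level(rng):
    """A 2-level configuration model plus the one-single subspace whose
    adiabatic part is tuned so the SMA first term equals (H_QQ - E0)^2 and
    whose diagonal elements use H_00 = E0."""
    from dressedtddft.ci_oracle import ModelHamiltonian

    e0 = float(rng.uniform(-1.0, 0.0))
    h_qq = e0 + float(rng.uniform(0.25, 0.6))
    h_dd = e0 + float(rng.uniform(0.3, 0.8))
    h_qd = float(rng.uniform(0.02, 0.08)) * float(rng.choice([-1.0, 1.0]))
    nu_q = float(rng.uniform(0.2, 0.6))
    model = ModelHamiltonian(np.array([[h_qq, h_qd], [h_qd, h_dd]]), e0)
    f_adia = ((h_qq - e0) ** 2 - nu_q**2) / (4.0 * nu_q)
    orbitals = OrbitalSpectrum(np.array([-0.5 * nu_q, 0.5 * nu_q]), 1)
    subspace = build_subspace(
        orbitals, [(0, 1)], (0, 1),
        a_adia=np.array([[nu_q + 2.0 * f_adia]]),
        b_adia=np.array([[2.0 * f_adia]]),
        h_qd=np.array([h_qd]),
        omega_adia=np.array([nu_q]),
        diag_elements=DiagonalElements(
            h_qq=np.array([[h_qq]]), h_dd=h_dd, h_00=e0
        ),
    )
    return model, subspace


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
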