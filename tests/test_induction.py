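"""Thole induction: polarizabilities, screened fields, tensors, solve,
gradients, and the textbook point-dipole cross-check."""

import numpy as np
import pytest
from scipy.integrate import quad

from emlekit import (
    AtomParams,
    GlobalParams,
    MMEnvironment,
    build_polarization_system,
    induction_energy,
    induction_gradients,
    polarizability,
    screened_field,
    solve_induction,
    thole_tensor,
)
from emlekit.induction import PolarizationSystem, mm_fields
from emlekit.fixtures import (
    DensitySpec,
    fd_gradient,
    make_charge_shell,
    make_solute_fixture,
    quadrature_coulomb,
)

from conftest import random_rotation, rotate_environment


def _atom(s=0.4, q_val=-2.0, k_Z=0.05):
    return AtomParams(
        element="C", q_core=4.0, q_val=q_val, s=s, chi=0.2,
        hardness_J=0.4, k_Z=k_Z,
    )


class TestPolarizability:
    def test_cubic_scaling_with_width(self):
        a1 = polarizability(_atom(s=0.4))
        a2 = polarizability(_atom(s=0.8))
        assert a2 == pytest.approx(8.0 * a1, rel=1e-12)

    def test_linear_in_k_Z(self):
        a1 = polarizability(_atom(k_Z=0.5))
        a2 = polarizability(_atom(k_Z=1.0))
        assert a1 == pytest.approx(0.5 * a2, rel=1e-12)

    def test_moment_integral_oracle(self):
        """alpha(k_Z=1, N=2, s=1) equals N<r^3> of the normalized
        exponential density, computed by numerical quadrature."""
        s = 1.0
        norm = 1.0 / (8.0 * np.pi * s**3)
        moment, _ = quad(
            lambda r: 4.0 * np.pi * r**2 * r**3 * norm * np.exp(-r / s),
            0,
            200,
            limit=200,
        )
        expected = 2.0 * moment
        got = polarizability(_atom(s=1.0, q_val=-2.0, k_Z=1.0))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            polarizability(_atom(q_val=0.5))  # no valence electrons

    def test_zero_k_Z_gives_zero_alpha(self):
        assert polarizability(_atom(k_Z=0.0)) == 0.0


class TestScreenedField:
    def test_bare_coulomb_at_long_range(self):
        s, a_damp, q = 1.0, 2.0, 1.3
        r = 100.0 * s
        field = screened_field(q, s, a_damp, [r, 0.0, 0.0])
        bare = q / r**2
        assert field[0] == pytest.approx(bare, rel=1e-8)
        assert abs(field[1]) < 1e-16 and abs(field[2]) < 1e-16

    def test_fully_screened_at_center(self):
        mags = [
            np.linalg.norm(screened_field(1.0, 1.0, 2.0, [r, 0, 0]))
            for r in (1.0, 0.1, 0.01)
        ]
        # near the center the magnitude decays linearly, |E| ~ q r / (6 w^3)
        assert mags[0] > mags[1] > mags[2]
        assert mags[2] == pytest.approx(mags[1] / 10.0, rel=0.05)
        assert mags[2] < 1e-3

    def test_matches_derivative_of_quadrature_potential(self):
        """Field = -d/dr of the numerically integrated potential of a
        Slater density with width a_damp * s."""
        q, s, a_damp, r = 1.0, 1.0, 2.0, 3.0
        spec = DensitySpec("slater", q, a_damp * s)
        h = 1e-5
        dV = (
            quadrature_coulomb(spec, r + h) - quadrature_coulomb(spec, r - h)
        ) / (2 * h)
        field = screened_field(q, s, a_damp, [r, 0.0, 0.0])
        assert field[0] == pytest.approx(-dV, rel=1e-8)

    def test_a_damp_zero_disables_screening(self):
        f = screened_field(1.0, 1.0, 0.0, [0.5, 0.0, 0.0])
        assert f[0] == pytest.approx(1.0 / 0.25, rel=1e-14)


class TestTholeTensor:
    def test_matches_undamped_at_large_separation(self):
        rvec = np.array([0.0, 0.0, 30.0])
        T = thole_tensor(5.0, 5.0, rvec, a=0.39)
        r = 30.0
        rhat = rvec / r
        undamped = (3.0 * np.outer(rhat, rhat) - np.eye(3)) / r**3
        assert np.abs(T - undamped).max() < 1e-10 * np.abs(undamped).max()

    def test_axial_block_diagonal(self):
        rvec = np.array([0.0, 0.0, 2.0])
        a = 0.39
        alpha = 4.0
        T = thole_tensor(alpha, alpha, rvec, a)
        off = T - np.diag(np.diag(T))
        assert np.abs(off).max() < 1e-15
        u = 2.0 / (alpha * alpha) ** (1 / 6)
        au3 = a * u**3
        lam3 = 1 - np.exp(-au3)
        lam5 = 1 - (1 + au3) * np.exp(-au3)
        r3 = 8.0
        expected = np.array(
            [-lam3 / r3, -lam3 / r3, (3 * lam5 - lam3) / r3]
        )
        assert np.abs(np.diag(T) - expected).max() < 1e-14

    def test_trace(self):
        """Undamped trace is 0; damped trace follows 3(λ5-λ3)/r³, checked
        against elementwise construction."""
        rvec = np.array([1.0, -2.0, 0.5])
        r = np.linalg.norm(rvec)
        T_undamped = thole_tensor(4.0, 4.0, rvec, a=np.inf)
        assert abs(np.trace(T_undamped)) < 1e-14
        a = 0.39
        T = thole_tensor(4.0, 4.0, rvec, a)
        u = r / 16.0 ** (1 / 6)
        au3 = a * u**3
        lam3 = 1 - np.exp(-au3)
        lam5 = 1 - (1 + au3) * np.exp(-au3)
        assert np.trace(T) == pytest.approx(
            3.0 * (lam5 - lam3) / r**3, rel=1e-12
        )

    def test_symmetry(self):
        T = thole_tensor(3.0, 7.0, np.array([1.2, 0.4, -0.9]))
        assert np.abs(T - T.T).max() < 1e-16


class TestSolveInduction:
    def test_isolated_atom_mu_equals_alpha_E(self):
        system = PolarizationSystem(
            alpha=np.array([1.0]),
            T=np.zeros((1, 1, 3, 3)),
            fields=np.array([[0.0, 0.0, 0.1]]),
            a_damp=2.0,
        )
        mu, e_ind = solve_induction(system)
        assert np.abs(mu - [[0.0, 0.0, 0.1]]).max() < 1e-14
        assert e_ind == pytest.approx(-0.5 * 1.0 * 0.1**2)

    def test_far_charge_polarization_energy_limit(self):
        """Single neutral atom + distant charge: e_ind -> -alpha q^2/(2 r^4)."""
        ml = make_solute_fixture(1, seed=3)
        alpha = polarizability(ml.params[0])
        q, r = 0.9, 60.0
        mm = MMEnvironment([q], [[r, 0.0, 0.0]])
        e_ind, _ = induction_energy(ml, mm)
        assert e_ind == pytest.approx(
            -alpha * q**2 / (2.0 * r**4), rel=1e-6
        )

    def test_two_evaluation_routes_agree(self):
        """-(1/2) mu.E versus explicitly summing screened dipole potentials
        at the MM sites and halving."""
        ml = make_solute_fixture(4, seed=8)
        mm = make_charge_shell(5, radius=7.0, seed=9)
        gp = GlobalParams()
        system, mask = build_polarization_system(ml, mm, gp)
        mu, e_ind = solve_induction(system)
        coords = ml.coords[mask]
        s = ml.s[mask]
        from emlekit.static_electrostatics import enclosed_fraction

        interaction = 0.0
        for j in range(mm.n_charges):
            for i in range(coords.shape[0]):
                rvec = mm.coords[j] - coords[i]
                r = np.linalg.norm(rvec)
                g = float(enclosed_fraction(r / (gp.a_damp * s[i])))
                phi_dip = float(np.dot(mu[i], rvec)) * g / r**3
                interaction += mm.charges[j] * phi_dip
        assert e_ind == pytest.approx(0.5 * interaction, abs=1e-10)

    def test_induction_energy_is_stabilizing(self):
        for seed in range(6):
            ml = make_solute_fixture(5, seed=seed)
            mm = make_charge_shell(8, radius=8.0, seed=seed + 50)
            e_ind, _ = induction_energy(ml, mm)
            assert e_ind <= 0.0

    def test_bilinear_in_mm_charges(self):
        ml = make_solute_fixture(3, seed=17)
        mm = make_charge_shell(6, radius=7.5, seed=18)
        e1, _ = induction_energy(ml, mm)
        mm2 = MMEnvironment(2.0 * mm.charges, mm.coords)
        e2, _ = induction_energy(ml, mm2)
        assert e2 == pytest.approx(4.0 * e1, rel=1e-10)

    def test_rigid_motion_invariance_and_covariant_dipoles(self):
        ml = make_solute_fixture(4, seed=19)
        mm = make_charge_shell(5, radius=7.0, seed=20)
        e0, mu0 = induction_energy(ml, mm)
        R = random_rotation(21)
        shift = np.array([1.0, 2.0, -0.5])
        ml2 = ml.with_coords(ml.coords @ R.T + shift)
        mm2 = rotate_environment(mm, R, shift)
        e1, mu1 = induction_energy(ml2, mm2)
        assert e1 == pytest.approx(e0, abs=1e-12)
        assert np.abs(mu1 - mu0 @ R.T).max() < 1e-10

    def test_matches_textbook_point_dipole_model(self):
        """Screening and damping disabled: independent plain polarizable
        point-dipole implementation must agree."""
        ml = make_solute_fixture(4, seed=23)
        mm = make_charge_shell(6, radius=9.0, seed=24)
        gp = GlobalParams(a_damp=0.0, thole_a=np.inf)
        e_ind, _ = induction_energy(ml, mm, gp)

        # independent textbook implementation
        alpha = np.array([polarizability(p) for p in ml.params])
        n = ml.n_atoms
        E = np.zeros((n, 3))
        for i in range(n):
            for j in range(mm.n_charges):
                rv = ml.coords[i] - mm.coords[j]
                r = np.linalg.norm(rv)
                E[i] += mm.charges[j] * rv / r**3
        B = np.zeros((3 * n, 3 * n))
        for i in range(n):
            B[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = np.eye(3) / alpha[i]
            for j in range(n):
                if i == j:
                    continue
                rv = ml.coords[i] - ml.coords[j]
                r = np.linalg.norm(rv)
                rhat = rv / r
                Tij = (3.0 * np.outer(rhat, rhat) - np.eye(3)) / r**3
                B[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = -Tij
        mu = np.linalg.solve(B, E.ravel()).reshape(n, 3)
        e_ref = -0.5 * float(np.sum(mu * E))
        assert e_ind == pytest.approx(e_ref, rel=1e-10)


class TestInductionGradients:
    def _case(self, seed, n=4, m=5):
        ml = make_solute_fixture(n, seed=seed)
        mm = make_charge_shell(m, radius=7.0, seed=seed + 200)
        return ml, mm

    def test_translation_invariance(self):
        ml, mm = self._case(31)
        gml, gmm = induction_gradients(ml, mm)
        assert np.abs(gml.sum(0) + gmm.sum(0)).max() < 1e-9

    def test_matches_finite_differences(self):
        ml, mm = self._case(32)
        gp = GlobalParams()
        gml, gmm = induction_gradients(ml, mm, gp)
        fd_ml = fd_gradient(
            lambda c: induction_energy(ml.with_coords(c), mm, gp)[0],
            ml.coords,
            richardson=True,
        )
        fd_mm = fd_gradient(
            lambda c: induction_energy(
                ml, MMEnvironment(mm.charges, c), gp
            )[0],
            mm.coords,
            richardson=True,
        )
        scale = max(np.abs(fd_ml).max(), np.abs(fd_mm).max())
        assert np.abs(gml - fd_ml).max() < 1e-6 * scale
        assert np.abs(gmm - fd_mm).max() < 1e-6 * scale

    def test_rotation_covariance(self):
        ml, mm = self._case(33)
        gml, gmm = induction_gradients(ml, mm)
        R = random_rotation(34)
        ml2 = ml.with_coords(ml.coords @ R.T)
        mm2 = MMEnvironment(mm.charges, mm.coords @ R.T)
        gml2, gmm2 = induction_gradients(ml2, mm2)
        assert np.abs(gml2 - gml @ R.T).max() < 1e-9
        assert np.abs(gmm2 - gmm @ R.T).max() < 1e-9
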