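"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from emlekit import GlobalParams, MMEnvironment
from emlekit.charge_equilibration import qeq_matrix
from emlekit.fixtures import make_charge_shell, make_solute_fixture


@pytest.fixture
def small_system():
    """A 4-atom ML region inside an 6-charge shell."""
    ml = make_solute_fixture(4, seed=11)
    mm = make_charge_shell(6, radius=8.0, net_charge=0.0, seed=12)
    return ml, mm


@pytest.fixture
def global_params():
    return GlobalParams()


def random_rotation(seed: int) -> np.ndarray:
    """A uniformly random proper rotation matrix."""
    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()


def rigid_transform(coords, R, shift):
    return coords @ R.T + shift


def qeq_bruteforce(system, coords) -> np.ndarray:
    """Constrained numerical minimizer oracle for charge equilibration.

    Minimizes chi.q + 1/2 q A q subject to sum(q) = Q by parametrizing the
    constraint surface (q = q_uniform + Z t with Z an orthonormal basis of
    the sum-zero subspace) and running BFGS to a tight gradient tolerance.
    Independent of the bordered linear solve under test (it only shares the
    matrix assembly, which is itself pinned by the quadrature oracle).
    """
    A = qeq_matrix(system, coords)
    n = system.n_atoms
    q0 = np.full(n, system.total_charge / n)
    if n == 1:
        return q0
    # orthonormal basis of { t : sum(t) = 0 }
    ones = np.ones((n, 1)) / np.sqrt(n)
    Z = np.linalg.svd(np.eye(n) - ones @ ones.T)[0][:, : n - 1]

    def energy(t):
        q = q0 + Z @ t
        return float(system.chi @ q + 0.5 * q @ A @ q)

    def grad(t):
        q = q0 + Z @ t
        return Z.T @ (system.chi + A @ q)

    res = minimize(
        energy,
        np.zeros(n - 1),
        jac=grad,
        method="BFGS",
        options={"gtol": 1e-13, "maxiter": 1000},
    )
    return q0 + Z @ res.x


def rotate_environment(mm: MMEnvironment, R, shift) -> MMEnvironment:
    return MMEnvironment(mm.charges, rigid_transform(mm.coords, R, shift))
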