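"""Charge equilibration (QEq) with Gaussian-shielded Coulomb interactions.

Total atomic charges respond to geometry by minimizing

    E(q) = sum_i [ chi_i q_i + 1/2 A_ii q_i^2 ] + sum_{i<j} q_i A_ij q_j

subject to sum_i q_i = Q, where the off-diagonal coupling is the Coulomb
interaction of two normalized spherical Gaussian charge densities
rho_i ∝ exp(-r² / 2σ_i²):

    A_ij = erf( r_ij / sqrt(2 (σ_i² + σ_j²)) ) / r_ij,

continuous at r = 0 and tending to 1/r at long range.  The shielding width
is proportional to the MBIS valence shell width, σ_i = a_QEq · s_i.  The
diagonal self-term is the hardness J_i plus the r→0 limit of the Gaussian
self-interaction, 1/(σ_i √π), which makes the diagonal the exact r→0 limit
of the off-diagonal coupling when J_i = 0.

The constrained quadratic minimization is a single bordered (KKT) linear
solve:

    [ A   1 ] [ q ]   [ -chi ]
    [ 1ᵀ  0 ] [ λ ] = [  Q   ].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .core_types import EmleError, GlobalParams, MLRegion

__all__ = [
    "QEqSingularError",
    "QEqSystem",
    "gaussian_interaction",
    "gaussian_self_interaction",
    "qeq_system_from_region",
    "qeq_matrix",
    "solve_qeq",
    "solve_qeq_adjoint",
    "qeq_matrix_gradient_term",
]

# condition number above which the bordered KKT matrix is declared singular
_COND_LIMIT = 1e12


class QEqSingularError(EmleError):
    """Singular or numerically ill-conditioned QEq (KKT) system."""

    def __init__(self, cond: float):
        self.condition_number = cond
        super().__init__(
            f"QEq KKT matrix is singular or ill-conditioned "
            f"(condition number {cond:.3e})"
        )


@dataclass(frozen=True)
class QEqSystem:
    """Electronegativities, hardnesses, shielding widths and the constraint.

    chi in hartree/e, J in hartree/e², sigma in bohr (> 0), total_charge
    in e.
    """

    chi: np.ndarray
    hardness_J: np.ndarray
    sigma: np.ndarray
    total_charge: float

    def __post_init__(self):
        object.__setattr__(self, "chi", np.asarray(self.chi, float))
        object.__setattr__(
            self, "hardness_J", np.asarray(self.hardness_J, float)
        )
        object.__setattr__(self, "sigma", np.asarray(self.sigma, float))
        if not np.all(self.sigma > 0):
            raise ValueError("all shielding widths sigma must be > 0")

    @property
    def n_atoms(self) -> int:
        return int(self.chi.shape[0])


def qeq_system_from_region(
    ml: MLRegion, global_params: GlobalParams = GlobalParams()
) -> QEqSystem:
    """Build the QEq system for an ML region (σ_i = a_QEq · s_i)."""
    return QEqSystem(
        chi=ml.chi,
        hardness_J=ml.hardness_J,
        sigma=global_params.a_qeq * ml.s,
        total_charge=ml.total_charge,
    )


def gaussian_interaction(sigma_a, sigma_b, r):
    """Coulomb interaction (hartree/e²) of two unit Gaussian densities.

    erf(r/√(2(σ_a²+σ_b²)))/r, with the analytic r→0 limit
    √(2/π)/√(σ_a²+σ_b²).  Vectorized.
    """
    sigma_a = np.asarray(sigma_a, float)
    sigma_b = np.asarray(sigma_b, float)
    r = np.asarray(r, float)
    gamma = np.sqrt(2.0 * (sigma_a**2 + sigma_b**2))
    sa, sb, r_b, g = np.broadcast_arrays(sigma_a, sigma_b, r, gamma)
    out = np.empty(r_b.shape)
    zero = r_b == 0.0
    out[zero] = 2.0 / (np.sqrt(np.pi) * g[zero])
    nz = ~zero
    out[nz] = erf(r_b[nz] / g[nz]) / r_b[nz]
    if out.ndim == 0:
        return float(out)
    return out


def gaussian_self_interaction(sigma):
    """r→0 self-interaction of a unit Gaussian density: 1/(σ√π)."""
    return 1.0 / (np.asarray(sigma, float) * np.sqrt(np.pi))


def qeq_matrix(system: QEqSystem, coords: np.ndarray) -> np.ndarray:
    """Symmetric interaction matrix A (diagonal J + self, Gaussian Coulomb
    off-diagonal)."""
    coords = np.asarray(coords, float)
    n = system.n_atoms
    rvec = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((rvec**2).sum(-1))
    A = gaussian_interaction(
        system.sigma[:, None], system.sigma[None, :], r
    )
    A = np.asarray(A)
    np.fill_diagonal(
        A, system.hardness_J + gaussian_self_interaction(system.sigma)
    )
    return A


def _kkt(system: QEqSystem, coords: np.ndarray) -> np.ndarray:
    n = system.n_atoms
    A = qeq_matrix(system, coords)
    K = np.zeros((n + 1, n + 1))
    K[:n, :n] = A
    K[:n, n] = 1.0
    K[n, :n] = 1.0
    return K


def solve_qeq(system: QEqSystem, coords: np.ndarray) -> np.ndarray:
    """Charges minimizing the QEq energy under the total-charge constraint.

    Direct bordered-matrix solve; raises :class:`QEqSingularError` (with the
    condition number) if the KKT matrix is singular or ill-conditioned.
    The returned charges satisfy ``sum(q) == total_charge`` to solver
    tolerance (≤ 1e-12 for well-conditioned systems).
    """
    n = system.n_atoms
    K = _kkt(system, coords)
    cond = np.linalg.cond(K)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise QEqSingularError(float(cond))
    rhs = np.concatenate([-system.chi, [system.total_charge]])
    sol = np.linalg.solve(K, rhs)
    return sol[:n]


def solve_qeq_adjoint(
    system: QEqSystem, coords: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Adjoint vector y for differentiating through the QEq solve.

    For a downstream quantity E with ∂E/∂q = w, the geometric response
    contribution is  wᵀ (dq/dx) = -yᵀ (dA/dx) q  where y solves the same
    KKT system with right-hand side (w, 0).
    """
    n = system.n_atoms
    K = _kkt(system, coords)
    rhs = np.concatenate([np.asarray(w, float), [0.0]])
    sol = np.linalg.solve(K, rhs)
    return sol[:n]


def qeq_matrix_gradient_term(
    system: QEqSystem, coords: np.ndarray, y: np.ndarray, q: np.ndarray
) -> np.ndarray:
    """Per-atom gradient contribution -yᵀ (dA/dx_k) q (hartree/bohr).

    Uses d/dr [erf(r/γ)/r] = (2/(γ√π)) e^{-r²/γ²}/r - erf(r/γ)/r².
    Pairwise equal-and-opposite, so the contributions sum to zero.
    """
    coords = np.asarray(coords, float)
    n = system.n_atoms
    grad = np.zeros((n, 3))
    if n == 1:
        return grad
    rvec = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((rvec**2).sum(-1))
    np.fill_diagonal(r, 1.0)  # dummy; diagonal excluded below
    gamma = np.sqrt(
        2.0 * (system.sigma[:, None] ** 2 + system.sigma[None, :] ** 2)
    )
    u = r / gamma
    dA_dr = (2.0 / (gamma * np.sqrt(np.pi))) * np.exp(-(u**2)) / r - erf(
        u
    ) / r**2
    np.fill_diagonal(dA_dr, 0.0)
    y = np.asarray(y, float)
    q = np.asarray(q, float)
    # grad_k = -sum_{j != k} (y_k q_j + y_j q_k) A'(r_kj) rhat_kj
    S = y[:, None] * q[None, :] + y[None, :] * q[:, None]
    coeff = -S * dA_dr / r
    np.fill_diagonal(coeff, 0.0)
    grad = np.einsum("ij,ijk->ik", coeff, rvec)
    return grad
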