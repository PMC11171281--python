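"""Total-energy assembly: in-vacuo backend plus EMLE embedding.

The total ML/MM energy is E_vac(ML coords) + E_embed(ML, MM), with the
embedding computed in one of three modes:

``mechanical_mm``
    Fixed per-atom point charges (the ``q_mm`` column of the parameter
    file) in a plain Coulomb sum with the MM charges — the classical
    "mechanical embedding" baseline.
``emle_static``
    Charge equilibration plus the static Slater-density interaction.
``emle_total``
    ``emle_static`` plus Thole induction (with the polarization cost).

Backends are synchronous, stateless callables that see only the ML
coordinates — never any MM information.  A deterministic toy backend
(harmonic chain bonds + cosine dihedrals) ships for testing and for the
engine server; adapters for external ML potentials plug in behind the same
interface.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np

from .charge_equilibration import (
    qeq_matrix_gradient_term,
    qeq_system_from_region,
    solve_qeq,
    solve_qeq_adjoint,
)
from .core_types import (
    EmbeddingResult,
    EmleError,
    GeometryError,
    GlobalParams,
    MLRegion,
    MMEnvironment,
)
from .induction import induction_energy, induction_gradients
from .static_electrostatics import (
    slater_potential,
    static_energy,
    static_gradients,
)

__all__ = [
    "EmbeddingMode",
    "ModeError",
    "InVacuoBackend",
    "ToyBackend",
    "CalculationResult",
    "compute_embedding",
    "total_energy",
    "qeq_gradient_discrepancy",
]


class ModeError(EmleError):
    """Embedding mode incompatible with the supplied parameters."""


class EmbeddingMode(str, enum.Enum):
    MECHANICAL_MM = "mechanical_mm"
    EMLE_STATIC = "emle_static"
    EMLE_TOTAL = "emle_total"

    @classmethod
    def coerce(cls, value) -> "EmbeddingMode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ModeError(
                f"unknown embedding mode {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


#: An in-vacuo backend maps ML coordinates (n, 3) in bohr to
#: (energy in hartree, gradients (n, 3) in hartree/bohr).
InVacuoBackend = Callable[[np.ndarray], Tuple[float, np.ndarray]]


# ---------------------------------------------------------------------------
# Toy backend
# ---------------------------------------------------------------------------


class ToyBackend:
    """Deterministic toy in-vacuo potential with analytic gradients.

    Harmonic bonds between consecutive atoms along the input order,
    E_b = 1/2 k_bond (r - r0)², plus a cosine dihedral
    E_d = k_dih (1 + cos φ) on every consecutive quadruple.  Constants
    (a.u.): k_bond = 0.3 hartree/bohr², r0 = 2.5 bohr,
    k_dih = 0.005 hartree.  A trans (φ = 180°) chain at bond length r0 is
    an exact equilibrium.
    """

    k_bond = 0.3
    r0 = 2.5
    k_dih = 0.005

    def __call__(self, coords: np.ndarray) -> Tuple[float, np.ndarray]:
        coords = np.asarray(coords, float)
        n = coords.shape[0]
        if n < 1:
            raise GeometryError("toy backend needs at least one atom")
        energy = 0.0
        grad = np.zeros_like(coords)
        for i in range(n - 1):
            dvec = coords[i + 1] - coords[i]
            d = float(np.linalg.norm(dvec))
            energy += 0.5 * self.k_bond * (d - self.r0) ** 2
            gb = self.k_bond * (d - self.r0) * dvec / d
            grad[i + 1] += gb
            grad[i] -= gb
        for i in range(n - 3):
            e, g4 = self._dihedral(coords[i : i + 4])
            energy += e
            grad[i : i + 4] += g4
        return energy, grad

    def _dihedral(self, p: np.ndarray) -> Tuple[float, np.ndarray]:
        b1 = p[1] - p[0]
        b2 = p[2] - p[1]
        b3 = p[3] - p[2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = float(np.linalg.norm(b2))
        phi = float(
            np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2))
        )
        energy = self.k_dih * (1.0 + np.cos(phi))
        dE_dphi = -self.k_dih * np.sin(phi)
        n1sq = float(np.dot(n1, n1))
        n2sq = float(np.dot(n2, n2))
        dphi_dp1 = -nb2 / n1sq * n1
        dphi_dp4 = nb2 / n2sq * n2
        t = float(np.dot(b1, b2)) / nb2**2
        u = float(np.dot(b3, b2)) / nb2**2
        dphi_dp2 = -(1.0 + t) * dphi_dp1 + u * dphi_dp4
        dphi_dp3 = t * dphi_dp1 - (1.0 + u) * dphi_dp4
        g = dE_dphi * np.stack([dphi_dp1, dphi_dp2, dphi_dp3, dphi_dp4])
        return float(energy), g


# ---------------------------------------------------------------------------
# Embedding assembly
# ---------------------------------------------------------------------------


def _mechanical_embedding(ml: MLRegion, mm: MMEnvironment, gradients: bool):
    q_mm = [p.q_mm for p in ml.params]
    if any(q is None for q in q_mm):
        raise ModeError(
            "mechanical_mm embedding requires fixed q_mm charges for every "
            "ML atom (eighth parameter-file column)"
        )
    q = np.array(q_mm, float)
    n, m = ml.n_atoms, mm.n_charges
    if m == 0:
        return EmbeddingResult(
            0.0, 0.0, np.zeros((n, 3)), np.zeros((0, 3)),
            np.zeros((n, 3)), q,
        )
    rvec = ml.coords[:, None, :] - mm.coords[None, :, :]
    r = np.sqrt((rvec**2).sum(-1))
    if np.any(r == 0.0):
        raise GeometryError("ML atom coincides with MM site")
    e = float(np.einsum("i,ij,j->", q, 1.0 / r, mm.charges))
    grad_ml = np.zeros((n, 3))
    grad_mm = np.zeros((m, 3))
    if gradients:
        coeff = -q[:, None] * mm.charges[None, :] / r**3
        grad_ml = np.einsum("ij,ijk->ik", coeff, rvec)
        grad_mm = -np.einsum("ij,ijk->jk", coeff, rvec)
    return EmbeddingResult(e, 0.0, grad_ml, grad_mm, np.zeros((n, 3)), q)


def _static_qeq_gradient_term(ml, mm, qeq_sys, q) -> np.ndarray:
    """Adjoint contribution of the QEq charge response to the static
    gradient (exact path; ML atoms only — QEq is an in-vacuo property)."""
    # w_i = dE_static/dq_i = sum_j q_j * phi_slater(1, s_i, r_ij)
    rvec = ml.coords[:, None, :] - mm.coords[None, :, :]
    r = np.sqrt((rvec**2).sum(-1))
    phi = slater_potential(1.0, ml.s[:, None], r)
    w = np.einsum("ij,j->i", np.asarray(phi).reshape(ml.n_atoms, -1), mm.charges)
    y = solve_qeq_adjoint(qeq_sys, ml.coords, w)
    return qeq_matrix_gradient_term(qeq_sys, ml.coords, y, q)


def compute_embedding(
    ml: MLRegion,
    mm: MMEnvironment,
    mode=EmbeddingMode.EMLE_TOTAL,
    global_params: GlobalParams = GlobalParams(),
    gradients: bool = True,
    exact_qeq_gradients: bool = True,
) -> EmbeddingResult:
    """Embedding energy (and gradients) for one configuration.

    ``exact_qeq_gradients`` adds the adjoint term that differentiates the
    static energy through the charge-equilibration solve; switching it off
    selects the fast fixed-charge path (cheaper, but the gradients then are
    not the exact derivatives of the energy).
    """
    mode = EmbeddingMode.coerce(mode)
    n, m = ml.n_atoms, mm.n_charges
    if mode is EmbeddingMode.MECHANICAL_MM:
        return _mechanical_embedding(ml, mm, gradients)

    qeq_sys = qeq_system_from_region(ml, global_params)
    q = solve_qeq(qeq_sys, ml.coords)
    if m == 0:
        return EmbeddingResult(
            0.0, 0.0, np.zeros((n, 3)), np.zeros((0, 3)),
            np.zeros((n, 3)), q,
        )
    e_static = static_energy(ml, mm, q)
    grad_ml = np.zeros((n, 3))
    grad_mm = np.zeros((0, 3)) if m == 0 else np.zeros((m, 3))
    if gradients:
        grad_ml, grad_mm = static_gradients(ml, mm, q)
        if exact_qeq_gradients:
            grad_ml = grad_ml + _static_qeq_gradient_term(ml, mm, qeq_sys, q)

    e_ind = 0.0
    dipoles = np.zeros((n, 3))
    if mode is EmbeddingMode.EMLE_TOTAL:
        e_ind, dipoles = induction_energy(ml, mm, global_params)
        if gradients:
            gml_i, gmm_i = induction_gradients(ml, mm, global_params)
            grad_ml = grad_ml + gml_i
            grad_mm = grad_mm + gmm_i
    return EmbeddingResult(e_static, e_ind, grad_ml, grad_mm, dipoles, q)


@dataclass
class CalculationResult:
    """Total energy decomposition for one engine call."""

    e_total: float
    e_vac: float
    embedding: EmbeddingResult
    grad_ml: np.ndarray
    grad_mm: np.ndarray


def total_energy(
    ml: MLRegion,
    mm: MMEnvironment,
    backend: InVacuoBackend,
    mode=EmbeddingMode.EMLE_TOTAL,
    global_params: GlobalParams = GlobalParams(),
    gradients: bool = True,
    exact_qeq_gradients: bool = True,
) -> CalculationResult:
    """E_vac + E_embed with gradients on ML atoms and MM sites.

    The backend receives only the ML coordinates.  For an empty MM
    environment the result is exactly the in-vacuo one in every mode.
    """
    e_vac, grad_vac = backend(ml.coords)
    emb = compute_embedding(
        ml, mm, mode, global_params, gradients, exact_qeq_gradients
    )
    grad_ml = np.asarray(grad_vac, float) + emb.grad_ml
    return CalculationResult(
        e_total=float(e_vac) + emb.e_embedding,
        e_vac=float(e_vac),
        embedding=emb,
        grad_ml=grad_ml,
        grad_mm=emb.grad_mm,
    )


def qeq_gradient_discrepancy(
    ml: MLRegion,
    mm: MMEnvironment,
    global_params: GlobalParams = GlobalParams(),
) -> float:
    """Diagnostic: max |exact - fixed-charge| static gradient component
    (hartree/bohr), i.e. the size of the neglected QEq response term."""
    if mm.n_charges == 0:
        return 0.0
    qeq_sys = qeq_system_from_region(ml, global_params)
    q = solve_qeq(qeq_sys, ml.coords)
    term = _static_qeq_gradient_term(ml, mm, qeq_sys, q)
    return float(np.abs(term).max())
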