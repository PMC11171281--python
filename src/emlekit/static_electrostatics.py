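"""Static embedding energy: MM point charges against core + Slater densities.

The in-vacuo electronic density of the ML region is approximated as a sum of
atomic densities, each a core point charge plus a spherical valence Slater
shell rho(r) = q_val / (8 pi s^3) * exp(-r/s).  The electrostatic potential
of such a shell has the closed form

    V(r) = (q/r) * (1 - exp(-r/s) * (1 + r/(2 s))),

finite at the origin (V(0) = q/(2 s)) and tending to the bare Coulomb
potential q/r at long range.  The deviation at short range is the charge
penetration effect.  By Gauss's law the radial field is the bare field
scaled by the enclosed-charge fraction

    g(x) = 1 - exp(-x) * (1 + x + x^2/2),  x = r/s.

The static embedding energy is the sum over (ML atom, MM site) pairs of the
MM charge times the core point-charge potential plus the valence-shell
potential, with the valence charge shifted so that the atom's total charge
equals the charge-equilibration result (the core charge is held fixed; core
electrons are inert in the MBIS picture).
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .core_types import GeometryError, MLRegion, MMEnvironment

__all__ = [
    "slater_potential",
    "slater_potential_derivative",
    "enclosed_fraction",
    "static_energy",
    "static_gradients",
]


def _penetration_factor(x: np.ndarray) -> np.ndarray:
    """f(x) = 1 - e^{-x} (1 + x/2), the potential attenuation factor.

    Series branch for small x avoids catastrophic cancellation
    (f = x/2 - x^3/12 + x^4/24 - ...).
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-3
    xs = x[small]
    out[small] = xs / 2 - xs**3 / 12 + xs**4 / 24
    xl = x[~small]
    out[~small] = 1.0 - np.exp(-xl) * (1.0 + 0.5 * xl)
    return out


def enclosed_fraction(x: np.ndarray) -> np.ndarray:
    """g(x) = 1 - e^{-x}(1 + x + x²/2): charge fraction of a Slater shell
    enclosed within scaled radius x = r/s.  Monotone from 0 to 1."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-2
    xs = x[small]
    out[small] = xs**3 / 6 - xs**4 / 8 + xs**5 / 20
    xl = x[~small]
    out[~small] = 1.0 - np.exp(-xl) * (1.0 + xl + 0.5 * xl**2)
    return out


def slater_potential(q, s, r):
    """Electrostatic potential (hartree/e) at distance r of a Slater shell.

    Parameters: total shell charge ``q`` (e), width ``s`` (bohr, ``s = 0``
    gives the point-charge limit) and separation ``r`` (bohr).  Vectorized
    over any broadcastable combination.  Finite at r = 0 (``q/(2s)``);
    exactly ``q/r`` for ``s = 0``.
    """
    q, s, r = np.broadcast_arrays(
        np.asarray(q, float), np.asarray(s, float), np.asarray(r, float)
    )
    out = np.empty(q.shape)
    point = s == 0.0
    with np.errstate(divide="ignore"):
        out[point] = q[point] / r[point]
    sp = s[~point]
    rp = r[~point]
    qp = q[~point]
    x = rp / sp
    origin = rp == 0.0
    res = np.empty_like(rp)
    res[origin] = qp[origin] / (2.0 * sp[origin])
    nx = ~origin
    res[nx] = qp[nx] * _penetration_factor(x[nx]) / rp[nx]
    out[~point] = res
    if out.ndim == 0:
        return float(out)
    return out


def slater_potential_derivative(q, s, r):
    """dV/dr of :func:`slater_potential` = -q g(r/s) / r² (r > 0)."""
    q = np.asarray(q, float)
    s = np.asarray(s, float)
    r = np.asarray(r, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(s > 0, enclosed_fraction(np.where(s > 0, r / np.where(s > 0, s, 1.0), 0.0)), 1.0)
    out = -q * g / r**2
    if out.ndim == 0:
        return float(out)
    return out


def _pair_geometry(ml: MLRegion, mm: MMEnvironment):
    """Separation vectors (n_ml, n_mm, 3) and distances; rejects r = 0."""
    rvec = ml.coords[:, None, :] - mm.coords[None, :, :]
    r = np.sqrt((rvec**2).sum(-1))
    if np.any(r == 0.0):
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise GeometryError(
            f"ML atom {i} coincides with MM site {j}: singular core term"
        )
    return rvec, r


def static_energy(
    ml: MLRegion, mm: MMEnvironment, charges: np.ndarray
) -> float:
    """Static embedding energy (hartree).

    ``charges`` are the per-ML-atom *total* charges (e), typically from the
    charge-equilibration solve.  The core charge of each atom is fixed; the
    valence shell carries ``q_i - q_core_i``.  Returns 0 for an empty MM
    environment.
    """
    if mm.n_charges == 0:
        return 0.0
    charges = np.asarray(charges, float)
    if charges.shape != (ml.n_atoms,):
        raise ValueError(
            f"need {ml.n_atoms} charges, got shape {charges.shape}"
        )
    _, r = _pair_geometry(ml, mm)
    q_core = ml.q_core
    q_val = charges - q_core
    # unit-charge shell potential per pair
    phi = slater_potential(1.0, ml.s[:, None], r)
    pair = q_core[:, None] / r + q_val[:, None] * phi
    return float(np.einsum("ij,j->", pair, mm.charges))


def static_gradients(
    ml: MLRegion,
    mm: MMEnvironment,
    charges: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`static_energy` (hartree/bohr).

    The charges are treated as geometry-independent (fast path).  The exact
    path, which also differentiates through the charge-equilibration solve,
    lives in the calculator: it adds an adjoint term (ML atoms only, since
    QEq is an in-vacuo property) on top of these fixed-charge gradients.

    Returns ``(grad_ml, grad_mm)``; their sum over all atoms/sites is the
    zero vector (translation invariance).
    """
    if mm.n_charges == 0:
        return np.zeros((ml.n_atoms, 3)), np.zeros((0, 3))
    charges = np.asarray(charges, float)
    rvec, r = _pair_geometry(ml, mm)
    q_core = ml.q_core
    q_val = charges - q_core
    with np.errstate(divide="ignore"):
        dpair_dr = (
            -q_core[:, None] / r**2
            + q_val[:, None]
            * slater_potential_derivative(1.0, ml.s[:, None], r)
        )
    # dE/dx_i = sum_j q_j * dpair/dr * rhat
    coeff = dpair_dr * mm.charges[None, :] / r
    grad_ml = np.einsum("ij,ijk->ik", coeff, rvec)
    grad_mm = -np.einsum("ij,ijk->jk", coeff, rvec)
    return grad_ml, grad_mm
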