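"""Synthetic inputs and independent brute-force oracles.

Everything here is generated programmatically — no downloads, no stored
data.  The per-element parameter table holds *physically plausible
magnitudes only*: it is a synthetic stand-in for trained EMLE parameters
and makes no accuracy claim about any real molecule.

The oracles (radial quadrature of densities, finite-difference gradients)
deliberately share no formula code with the production modules: the
quadrature integrates the density itself against the Coulomb kernel, so it
pins the closed-form potentials independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Tuple

import numpy as np
from scipy.integrate import quad

from .core_types import (
    AtomParams,
    EmleError,
    GlobalParams,
    MLRegion,
    MMEnvironment,
)

__all__ = [
    "FIXTURE_ELEMENT_TABLE",
    "DensitySpec",
    "QuadratureError",
    "make_solute_fixture",
    "make_charge_shell",
    "quadrature_coulomb",
    "quadrature_enclosed_charge",
    "quadrature_interaction",
    "fd_gradient",
    "toy_fes_potential",
    "sample_umbrella_windows",
]

# Plausible per-element EMLE parameters, synthetic fixture values only
# (NOT trained model parameters): q_core, q_val, s (bohr), chi (hartree/e),
# J (hartree/e²), k_Z, q_mm (e).
FIXTURE_ELEMENT_TABLE = {
    "H": dict(q_core=1.0, q_val=-0.92, s=0.32, chi=0.24, hardness_J=0.58,
              k_Z=0.12, q_mm=0.08),
    "C": dict(q_core=4.0, q_val=-4.05, s=0.44, chi=0.20, hardness_J=0.42,
              k_Z=0.045, q_mm=0.05),
    "N": dict(q_core=5.0, q_val=-5.30, s=0.41, chi=0.31, hardness_J=0.48,
              k_Z=0.030, q_mm=-0.30),
    "O": dict(q_core=6.0, q_val=-6.35, s=0.38, chi=0.36, hardness_J=0.52,
              k_Z=0.022, q_mm=-0.45),
    "S": dict(q_core=6.0, q_val=-6.10, s=0.55, chi=0.22, hardness_J=0.33,
              k_Z=0.035, q_mm=-0.12),
}

_FIXTURE_ELEMENTS = ("H", "C", "N", "O")


class QuadratureError(EmleError):
    """Requested quadrature tolerance not reached."""


# ---------------------------------------------------------------------------
# Geometry / environment generators
# ---------------------------------------------------------------------------


def make_solute_fixture(
    n_atoms: int, seed: int, min_dist: float = 1.5
) -> MLRegion:
    """Random chemically plausible ML region (coordinates in bohr).

    Atoms are grown sequentially near the previous atom, rejecting any
    placement closer than ``min_dist`` (default 1.5 bohr) to an existing
    atom.  Elements are drawn from H/C/N/O with fixture-table parameters.
    Deterministic for a given ``(n_atoms, seed)``.
    """
    if not 1 <= n_atoms <= 50:
        raise ValueError("n_atoms must be in [1, 50]")
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3)]
    while len(coords) < n_atoms:
        base = coords[rng.integers(len(coords))]
        trial = base + rng.uniform(-1.0, 1.0, 3) * 2.4
        d = np.linalg.norm(np.array(coords) - trial, axis=1)
        if np.all(d >= min_dist):
            coords.append(trial)
    elements = rng.choice(_FIXTURE_ELEMENTS, size=n_atoms)
    params = [
        AtomParams(element=el, **FIXTURE_ELEMENT_TABLE[el])
        for el in elements
    ]
    return MLRegion(np.array(coords), params)


def make_charge_shell(
    n_charges: int,
    radius: float,
    net_charge: float = 0.0,
    seed: int = 0,
    center: np.ndarray = None,
) -> MMEnvironment:
    """Point charges scattered on a sphere of the given radius (bohr).

    Charges are uniform random in [-0.85, 0.85] e (TIP3P-like magnitudes)
    and then shifted so their sum equals ``net_charge`` exactly.
    Deterministic under a fixed seed; ``n_charges = 0`` gives an empty
    environment.
    """
    if n_charges == 0:
        return MMEnvironment.empty()
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_charges, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    coords = v * radius
    if center is not None:
        coords = coords + np.asarray(center, float)
    q = rng.uniform(-0.85, 0.85, n_charges)
    q += (net_charge - q.sum()) / n_charges
    return MMEnvironment(q, coords)


# ---------------------------------------------------------------------------
# Quadrature oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DensitySpec:
    """A spherical model charge density centred at the origin.

    kind ``"slater"``: rho(r) = q e^{-r/s} / (8 pi s³);
    kind ``"gaussian"``: rho(r) = q e^{-r²/2σ²} / ((2π)^{3/2} σ³),
    with ``width`` = s or σ respectively and total charge ``q``.
    """

    kind: str
    q: float
    width: float

    def radial(self, r):
        if self.kind == "slater":
            return self.q * np.exp(-r / self.width) / (
                8.0 * np.pi * self.width**3
            )
        if self.kind == "gaussian":
            return self.q * np.exp(-(r**2) / (2.0 * self.width**2)) / (
                (2.0 * np.pi) ** 1.5 * self.width**3
            )
        raise ValueError(f"unknown density kind {self.kind!r}")

    @property
    def tail(self) -> float:
        """A radius beyond which the density is negligible."""
        return 60.0 * self.width


_QUAD_TOL = 1e-9


def quadrature_coulomb(spec: DensitySpec, d: float) -> float:
    """Electrostatic potential of ``spec`` at distance ``d``, by numerical
    integration of the density against the Coulomb kernel.

    The angular integral of 1/|r - r'| over a sphere reduces exactly to
    (r + d - |r - d|)/(2 r d) = 1/max(r, d); the radial integral is done
    with adaptive quadrature split at the kink r = d.  Absolute tolerance
    1e-9; raises :class:`QuadratureError` if the integrator cannot certify
    it.  This routine never calls the closed-form potentials.
    """

    def integrand(r):
        return 4.0 * np.pi * r**2 * spec.radial(r) / max(r, d)

    upper = max(spec.tail, 2.0 * d)
    pts = [d] if 0.0 < d < upper else None
    val, err = quad(
        integrand, 0.0, upper, points=pts, epsabs=_QUAD_TOL / 10,
        epsrel=1e-12, limit=400,
    )
    if err > _QUAD_TOL:
        raise QuadratureError(
            f"quadrature error estimate {err:.2e} exceeds {_QUAD_TOL}"
        )
    return float(val)


def quadrature_enclosed_charge(spec: DensitySpec, radius: float) -> float:
    """Charge of ``spec`` enclosed within ``radius`` (numeric radial
    integral, tolerance 1e-9)."""
    val, err = quad(
        lambda r: 4.0 * np.pi * r**2 * spec.radial(r),
        0.0,
        radius,
        epsabs=_QUAD_TOL / 10,
        epsrel=1e-12,
        limit=400,
    )
    if err > _QUAD_TOL:
        raise QuadratureError(
            f"quadrature error estimate {err:.2e} exceeds {_QUAD_TOL}"
        )
    return float(val)


def quadrature_interaction(
    spec_a: DensitySpec, spec_b: DensitySpec, d: float, n_mu: int = 64
) -> float:
    """Coulomb interaction energy of two spherical densities a distance
    ``d`` apart, by integrating density b against the numerically
    integrated potential of density a.

    The angular average uses Gauss–Legendre quadrature in cos θ (the
    integrand is smooth since the inner potential is finite everywhere);
    the radial integral is adaptive.  Independent of every closed form in
    the production modules.
    """
    nodes, weights = np.polynomial.legendre.leggauss(n_mu)

    def integrand(r):
        sep = np.sqrt(d**2 + r**2 - 2.0 * d * r * nodes)
        pot = np.array([quadrature_coulomb(spec_a, s) for s in sep])
        return 2.0 * np.pi * r**2 * spec_b.radial(r) * (weights * pot).sum()

    upper = max(spec_b.tail, 2.0 * d)
    val, err = quad(
        integrand, 0.0, upper, epsabs=1e-10, epsrel=1e-10, limit=200,
    )
    if err > 1e-8:
        raise QuadratureError(
            f"interaction quadrature error estimate {err:.2e} exceeds 1e-8"
        )
    return float(val)


# ---------------------------------------------------------------------------
# Finite-difference gradient oracle
# ---------------------------------------------------------------------------


def fd_gradient(
    energy_fn: Callable[[np.ndarray], float],
    coords: np.ndarray,
    step: float = 1e-4,
    richardson: bool = False,
) -> np.ndarray:
    """Central finite-difference gradient of a scalar function of (n, 3)
    coordinates (step in bohr).

    With ``richardson=True`` the estimate is Richardson-extrapolated,
    (4 D(h/2) - D(h)) / 3, removing the leading O(h²) error.
    Raises on non-finite energies.
    """
    coords = np.asarray(coords, float)

    def central(h):
        g = np.zeros_like(coords)
        for idx in np.ndindex(coords.shape):
            cp = coords.copy()
            cp[idx] += h
            ep = energy_fn(cp)
            cp[idx] -= 2 * h
            em = energy_fn(cp)
            if not (np.isfinite(ep) and np.isfinite(em)):
                raise EmleError("non-finite energy in finite differences")
            g[idx] = (ep - em) / (2 * h)
        return g

    if richardson:
        return (4.0 * central(step / 2) - central(step)) / 3.0
    return central(step)


# ---------------------------------------------------------------------------
# Toy free-energy-surface potential and umbrella sampler
# ---------------------------------------------------------------------------


def toy_fes_potential(phi_deg, psi_deg):
    """Smooth analytic 2D periodic potential (kcal/mol) on the torus.

    V = 1.6 (1 - cos φ) + 1.2 (1 - cos ψ) + 0.6 (1 - cos(φ - ψ)),
    angles in degrees.  Plays the role of a known dihedral free-energy
    surface for exercising the umbrella/WHAM pipeline.
    """
    phi = np.deg2rad(np.asarray(phi_deg, float))
    psi = np.deg2rad(np.asarray(psi_deg, float))
    return (
        1.6 * (1.0 - np.cos(phi))
        + 1.2 * (1.0 - np.cos(psi))
        + 0.6 * (1.0 - np.cos(phi - psi))
    )


def _wrap_deg(x):
    return (np.asarray(x, float) + 180.0) % 360.0 - 180.0


def sample_umbrella_windows(
    centers,
    k: float,
    n_samples: int,
    seed: int,
    temperature: float = 300.0,
    potential: Callable = toy_fes_potential,
    step_deg: float = 30.0,
    burn: int = 200,
    stride: int = 10,
):
    """Metropolis samples of ``potential`` + harmonic dihedral bias for a
    list of window centers (degrees).

    The bias is k/2 (Δφ² + Δψ²) with minimal-image wrapped differences in
    radians and ``k`` in kcal·mol⁻¹·rad⁻².  All windows are propagated as
    one vectorized walker ensemble; ``stride`` thins the chains to reduce
    autocorrelation.  Returns a list of (n_samples, 2) arrays (degrees),
    deterministic under a fixed seed.
    """
    from .umbrella_wham import KB_KCALMOL  # local import, no cycle at load

    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, float).reshape(-1, 2)
    n_win = centers.shape[0]
    beta = 1.0 / (KB_KCALMOL * temperature)

    def total_u(state):
        d = np.deg2rad(_wrap_deg(state - centers))
        bias = 0.5 * k * (d**2).sum(axis=1)
        return potential(state[:, 0], state[:, 1]) + bias

    state = centers.copy()
    u = total_u(state)
    out = np.empty((n_win, n_samples, 2))
    kept = 0
    step_count = 0
    total_steps = burn + stride * n_samples
    while kept < n_samples:
        prop = _wrap_deg(state + rng.normal(0.0, step_deg, state.shape))
        u_prop = total_u(prop)
        accept = rng.random(n_win) < np.exp(-beta * (u_prop - u))
        state[accept] = prop[accept]
        u[accept] = u_prop[accept]
        step_count += 1
        if step_count > burn and (step_count - burn) % stride == 0:
            out[:, kept, :] = state
            kept += 1
    return [out[w] for w in range(n_win)]


# ---------------------------------------------------------------------------
# Job-directory fixture (engine-interface format)
# ---------------------------------------------------------------------------


def make_job_dir(
    path,
    n_atoms: int = 5,
    n_charges: int = 12,
    seed: int = 7,
    radius: float = 9.0,
    global_params: GlobalParams = GlobalParams(),
) -> Path:
    """Write a complete synthetic engine job directory (coords.xyz,
    pointcharges.pc, params.emle) and return its path."""
    from .engine_interface import write_request  # avoid import cycle at load

    ml = make_solute_fixture(n_atoms, seed)
    mm = make_charge_shell(n_charges, radius, net_charge=0.0, seed=seed + 1)
    return write_request(path, ml, mm, global_params)
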