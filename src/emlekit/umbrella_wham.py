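"""2D periodic umbrella sampling and WHAM free-energy surfaces.

Umbrella windows restrain two periodic dihedral angles (φ, ψ) with
harmonic biases k/2 (Δφ² + Δψ²), Δ taken minimal-image on [-180°, 180°)
and k in kcal·mol⁻¹·rad⁻².  The weighted histogram analysis method (WHAM)
self-consistently unbiases and stitches the window histograms:

    P(b)  ∝  M(b) / Σ_w N_w exp(-β (U_w(b) - f_w)),
    exp(-β f_w) = Σ_b P(b) exp(-β U_w(b)),

iterated until the window offsets f_w are stationary.  The free energy
F = -kT ln P is anchored so its minimum over populated bins is zero;
unpopulated bins are NaN, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .core_types import EmleError

__all__ = [
    "KB_KCALMOL",
    "WhamError",
    "WhamConvergenceError",
    "UmbrellaWindow",
    "FESGrid",
    "wrap_angle",
    "make_window_grid",
    "wham_2d",
    "fes_rmse",
]

#: Boltzmann constant in kcal/(mol K).
KB_KCALMOL = 0.0019872041


class WhamError(EmleError):
    """Invalid WHAM input (empty windows, incompatible grids, ...)."""


class WhamConvergenceError(WhamError):
    """WHAM self-consistency not reached within max_iter."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        super().__init__(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last offset change {residual:.3e} kcal/mol)"
        )


def wrap_angle(x):
    """Wrap angles (degrees) to the minimal image on [-180, 180)."""
    return (np.asarray(x, float) + 180.0) % 360.0 - 180.0


@dataclass
class UmbrellaWindow:
    """One biased-sampling window.

    centers (φ0, ψ0) in degrees; force constant k in kcal·mol⁻¹·rad⁻²;
    samples an (n, 2) time series of (φ, ψ) in degrees.
    """

    centers: Tuple[float, float]
    k: float
    samples: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float).reshape(-1, 2)

    def bias(self, phi, psi) -> np.ndarray:
        """Bias energy (kcal/mol) at angles in degrees, periodic."""
        dphi = np.deg2rad(wrap_angle(np.asarray(phi) - self.centers[0]))
        dpsi = np.deg2rad(wrap_angle(np.asarray(psi) - self.centers[1]))
        return 0.5 * self.k * (dphi**2 + dpsi**2)


@dataclass
class FESGrid:
    """A 2D periodic free-energy surface on a regular (φ, ψ) bin grid.

    ``free_energy`` is (n_phi, n_psi) in kcal/mol with NaN for unpopulated
    bins and minimum 0 over populated bins; ``counts`` holds the total
    sample counts per bin.
    """

    edges_phi: np.ndarray
    edges_psi: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray

    @property
    def centers_phi(self) -> np.ndarray:
        return 0.5 * (self.edges_phi[:-1] + self.edges_phi[1:])

    @property
    def centers_psi(self) -> np.ndarray:
        return 0.5 * (self.edges_psi[:-1] + self.edges_psi[1:])

    @property
    def populated(self) -> np.ndarray:
        return ~np.isnan(self.free_energy)


def make_window_grid(
    n_per_angle: int, spacing: float
) -> List[Tuple[float, float]]:
    """Cartesian product of window centers covering the full torus.

    ``n_per_angle × spacing`` must equal 360° (complete periodic cover);
    e.g. 36 windows spaced 10° per angle give 1296 centers in total.
    Centers start at -180° along each angle.
    """
    if not np.isclose(n_per_angle * spacing, 360.0):
        raise WhamError(
            f"{n_per_angle} windows × {spacing}° = "
            f"{n_per_angle * spacing}° does not cover 360°"
        )
    ticks = -180.0 + spacing * np.arange(n_per_angle)
    return [(float(a), float(b)) for a in ticks for b in ticks]


def _histogram_2d(samples: np.ndarray, edges: np.ndarray) -> np.ndarray:
    h, _, _ = np.histogram2d(
        wrap_angle(samples[:, 0]), wrap_angle(samples[:, 1]),
        bins=[edges, edges],
    )
    return h


def wham_2d(
    windows: Sequence[UmbrellaWindow],
    bins: int = 72,
    temperature: float = 300.0,
    tol: float = 1e-7,
    max_iter: int = 100000,
) -> FESGrid:
    """Self-consistent WHAM integration of umbrella windows into an FES.

    ``bins`` square bins span [-180, 180)² (default 72 → 5° bins, matching
    a 10° window spacing).  Convergence: the largest change of any window
    free-energy offset f_w falls below ``tol`` (kcal/mol).  Deterministic
    given the inputs; raises :class:`WhamConvergenceError` carrying the
    last residual if ``max_iter`` is exhausted.
    """
    if len(windows) == 0:
        raise WhamError("no umbrella windows supplied")
    for i, w in enumerate(windows):
        if w.samples.shape[0] == 0:
            raise WhamError(f"window {i} (centers {w.centers}) is empty")
    if temperature <= 0:
        raise WhamError("temperature must be positive")
    beta = 1.0 / (KB_KCALMOL * temperature)
    edges = np.linspace(-180.0, 180.0, bins + 1)
    cphi = 0.5 * (edges[:-1] + edges[1:])
    mesh_phi, mesh_psi = np.meshgrid(cphi, cphi, indexing="ij")

    n_win = len(windows)
    counts = np.stack([_histogram_2d(w.samples, edges) for w in windows])
    n_samples = counts.reshape(n_win, -1).sum(axis=1)
    total = counts.sum(axis=0).ravel()  # M(b)
    bias = np.stack(
        [w.bias(mesh_phi, mesh_psi).ravel() for w in windows]
    )  # (n_win, n_bins)
    boltz = np.exp(-beta * bias)

    f = np.zeros(n_win)  # window offsets, kcal/mol
    residual = np.inf
    for _ in range(max_iter):
        denom = np.einsum("w,wb->b", n_samples * np.exp(beta * f), boltz)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(total > 0, total / denom, 0.0)
        z_w = boltz @ p
        f_new = -np.log(z_w) / beta
        f_new -= f_new[0]
        residual = float(np.abs(f_new - f).max())
        f = f_new
        if residual < tol:
            break
    else:
        raise WhamConvergenceError(residual, max_iter)

    with np.errstate(divide="ignore"):
        fes = np.where(total > 0, -np.log(p) / beta, np.nan)
    fes = fes.reshape(bins, bins)
    fes -= np.nanmin(fes)
    return FESGrid(
        edges_phi=edges,
        edges_psi=edges.copy(),
        free_energy=fes,
        counts=counts.sum(axis=0),
    )


def fes_rmse(
    fes_a: FESGrid,
    fes_b: FESGrid,
    cutoff: float = 20.0,
    align_offset: bool = True,
) -> float:
    """RMSE (kcal/mol) between two surfaces on identical binning.

    Only bins populated in both surfaces and below ``cutoff`` in the
    reference ``fes_b`` enter (high-energy bins carry few samples and
    large statistical error).  Free energies are defined up to a constant,
    so by default the optimal constant offset (the mean difference) is
    removed first; ``align_offset=False`` compares raw values.
    """
    if fes_a.free_energy.shape != fes_b.free_energy.shape or not np.allclose(
        fes_a.edges_phi, fes_b.edges_phi
    ):
        raise WhamError("FES grids have different binning")
    mask = (
        fes_a.populated & fes_b.populated & (fes_b.free_energy < cutoff)
    )
    if not np.any(mask):
        raise WhamError(
            f"no common populated bins below cutoff {cutoff} kcal/mol"
        )
    diff = fes_a.free_energy[mask] - fes_b.free_energy[mask]
    if align_offset:
        diff = diff - diff.mean()
    return float(np.sqrt(np.mean(diff**2)))
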