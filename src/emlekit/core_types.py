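"""Shared domain types, units, and the EMLE parameter-file dialect.

All internal quantities are in Hartree atomic units (hartree, bohr,
elementary charge).  Conversion to and from Å or kcal/mol happens only at
file and CLI boundaries, through :func:`convert_units`.

An EMLE calculation describes an embedded "ML region" (the subsystem treated
by a machine-learned or QM potential) surrounded by an "MM environment" of
fixed point charges.  Each ML atom carries a small set of physics-based
parameters derived from an in-vacuo density partitioning (MBIS): a core
point charge, a valence Slater-shell charge and width, an electronegativity
and hardness for charge equilibration, and a per-element polarizability
scaling factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "BOHR_TO_ANGSTROM",
    "HARTREE_TO_KCALMOL",
    "EmleError",
    "UnitError",
    "GeometryError",
    "ParameterFileError",
    "AtomParams",
    "GlobalParams",
    "MLRegion",
    "MMEnvironment",
    "EmbeddingResult",
    "convert_units",
    "read_parameter_file",
    "write_parameter_file",
]

# CODATA conversion factors.
BOHR_TO_ANGSTROM = 0.52917721067
HARTREE_TO_KCALMOL = 627.5094740631


class EmleError(Exception):
    """Base class for all errors raised by emlekit."""


class UnitError(EmleError):
    """Unknown unit tag or conversion between incompatible dimensions."""


class GeometryError(EmleError):
    """Invalid geometry (coincident atoms, singular separations, ...)."""


class ParameterFileError(EmleError):
    """Malformed EMLE parameter file."""


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

# unit tag -> (dimension, factor to the internal atomic unit)
_UNITS = {
    "bohr": ("length", 1.0),
    "angstrom": ("length", 1.0 / BOHR_TO_ANGSTROM),
    "A": ("length", 1.0 / BOHR_TO_ANGSTROM),
    "Å": ("length", 1.0 / BOHR_TO_ANGSTROM),
    "hartree": ("energy", 1.0),
    "kcal/mol": ("energy", 1.0 / HARTREE_TO_KCALMOL),
    "e": ("charge", 1.0),
}


def convert_units(value, from_unit: str, to_unit: str):
    """Convert ``value`` between unit tags.

    Supported tags: ``bohr``, ``angstrom``/``A``/``Å``, ``hartree``,
    ``kcal/mol``, ``e``.  Conversion is a single multiplication by CODATA
    factors, so round trips are exact to machine precision.

    Raises
    ------
    UnitError
        If a tag is unknown or the two tags have different dimensions.
    """
    try:
        dim_from, f_from = _UNITS[from_unit]
    except KeyError:
        raise UnitError(f"unknown unit tag {from_unit!r}") from None
    try:
        dim_to, f_to = _UNITS[to_unit]
    except KeyError:
        raise UnitError(f"unknown unit tag {to_unit!r}") from None
    if dim_from != dim_to:
        raise UnitError(
            f"cannot convert {from_unit!r} ({dim_from}) to {to_unit!r} ({dim_to})"
        )
    return np.asarray(value) * (f_from / f_to) if isinstance(
        value, (list, tuple, np.ndarray)
    ) else value * (f_from / f_to)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomParams:
    """Per-atom EMLE parameters.

    Attributes
    ----------
    element : str
        Chemical symbol.
    q_core : float
        Core charge in e (nucleus plus core electrons; positive).
    q_val : float
        Valence Slater-shell charge in e (typically negative).
        ``q_core + q_val`` is the atom's total in-vacuo partial charge.
    s : float
        Valence Slater-shell width in bohr (> 0).
    chi : float
        Electronegativity χ in hartree/e (first-order energy per charge).
    hardness_J : float
        Self-energy (hardness) J in hartree/e².
    k_Z : float
        Per-element polarizability scaling factor (dimensionless, ≥ 0;
        0 switches induction off for this atom).
    q_mm : float, optional
        Fixed point charge in e for mechanical (MM) embedding.
    """

    element: str
    q_core: float
    q_val: float
    s: float
    chi: float
    hardness_J: float
    k_Z: float
    q_mm: Optional[float] = None

    def __post_init__(self):
        if not self.s > 0:
            raise ValueError(f"Slater width s must be > 0, got {self.s}")
        if self.k_Z < 0:
            raise ValueError(f"k_Z must be >= 0, got {self.k_Z}")

    @property
    def q_total(self) -> float:
        """Total in-vacuo partial charge q_core + q_val (e)."""
        return self.q_core + self.q_val


@dataclass(frozen=True)
class GlobalParams:
    """Global EMLE model parameters (the parameter-file header).

    a_qeq scales the MBIS valence widths into the Gaussian shielding widths
    of charge equilibration (σ_i = a_qeq · s_i).  a_damp scales the valence
    widths for the field screening of the induction model; 2 avoids
    overpolarization.  thole_a is the dimensionless width of the cubic
    exponential (Thole) dipole–dipole damping.
    """

    a_qeq: float = 1.0
    a_damp: float = 2.0
    thole_a: float = 0.39

    def __post_init__(self):
        if not self.a_qeq > 0:
            raise ValueError("a_QEq must be > 0")
        if self.a_damp < 0:
            raise ValueError("a_damp must be >= 0")
        if not self.thole_a > 0:
            raise ValueError("thole_a must be > 0")


class MLRegion:
    """The embedded ML subsystem: coordinates plus per-atom parameters.

    Coordinates are in bohr.  Construction validates finiteness and rejects
    coincident atoms.
    """

    def __init__(
        self,
        coords: np.ndarray,
        params: Sequence[AtomParams],
        total_charge: Optional[float] = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise GeometryError(f"coords must be (n, 3), got {coords.shape}")
        n = coords.shape[0]
        if n < 1:
            raise GeometryError("ML region needs at least one atom")
        if len(params) != n:
            raise GeometryError(
                f"{len(params)} parameter records for {n} atoms"
            )
        if not np.all(np.isfinite(coords)):
            raise GeometryError("non-finite coordinates")
        if n > 1:
            diff = coords[:, None, :] - coords[None, :, :]
            d = np.sqrt((diff**2).sum(-1))
            iu = np.triu_indices(n, k=1)
            if np.any(d[iu] <= 0.0):
                i = int(np.argmin(d[iu]))
                a, b = iu[0][i], iu[1][i]
                raise GeometryError(f"coincident atoms {a} and {b}")
        self.coords = coords
        self.params = tuple(params)
        if total_charge is None:
            total_charge = float(round(sum(p.q_total for p in params)))
        self.total_charge = float(total_charge)

    @property
    def n_atoms(self) -> int:
        return len(self.params)

    @property
    def elements(self) -> tuple:
        return tuple(p.element for p in self.params)

    # convenience parameter arrays
    @property
    def q_core(self) -> np.ndarray:
        return np.array([p.q_core for p in self.params])

    @property
    def q_val(self) -> np.ndarray:
        return np.array([p.q_val for p in self.params])

    @property
    def s(self) -> np.ndarray:
        return np.array([p.s for p in self.params])

    @property
    def chi(self) -> np.ndarray:
        return np.array([p.chi for p in self.params])

    @property
    def hardness_J(self) -> np.ndarray:
        return np.array([p.hardness_J for p in self.params])

    @property
    def k_Z(self) -> np.ndarray:
        return np.array([p.k_Z for p in self.params])

    def with_coords(self, coords: np.ndarray) -> "MLRegion":
        """Same parameters at new coordinates (bohr)."""
        return MLRegion(coords, self.params, total_charge=self.total_charge)


class MMEnvironment:
    """The MM environment: point charges (e) at positions (bohr).

    May be empty, in which case every embedding energy is exactly zero.
    """

    def __init__(self, charges: np.ndarray, coords: np.ndarray):
        charges = np.atleast_1d(np.asarray(charges, dtype=float))
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if charges.shape[0] != coords.shape[0]:
            raise GeometryError(
                f"{charges.shape[0]} charges but {coords.shape[0]} positions"
            )
        if charges.size and not (
            np.all(np.isfinite(charges)) and np.all(np.isfinite(coords))
        ):
            raise GeometryError("non-finite MM charges or coordinates")
        self.charges = charges
        self.coords = coords

    @property
    def n_charges(self) -> int:
        return int(self.charges.shape[0])

    @classmethod
    def empty(cls) -> "MMEnvironment":
        return cls(np.zeros(0), np.zeros((0, 3)))


@dataclass
class EmbeddingResult:
    """Embedding energies, gradients and auxiliary quantities.

    Energies in hartree, gradients in hartree/bohr, dipoles in e·bohr,
    charges in e.  ``e_embedding == e_static + e_ind`` holds exactly; the
    polarization cost is folded into ``e_ind`` (the 1/2 factor).
    """

    e_static: float
    e_ind: float
    grad_ml: np.ndarray
    grad_mm: np.ndarray
    induced_dipoles: np.ndarray
    qeq_charges: np.ndarray

    @property
    def e_embedding(self) -> float:
        return self.e_static + self.e_ind


# ---------------------------------------------------------------------------
# Parameter file
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"a_QEq": "a_qeq", "a_damp": "a_damp", "thole_a": "thole_a"}


def read_parameter_file(path: Union[str, Path]):
    """Read an EMLE parameter file.

    Format: ``#`` comments and blank lines are ignored.  An optional header
    line of ``key value`` pairs sets the global parameters (keys ``a_QEq``,
    ``a_damp``, ``thole_a``).  Every other line is one ML atom, in the same
    order as the geometry::

        element  q_core  q_val  s  chi  J  k_Z  [q_mm]

    with widths in bohr and energies in hartree.  The optional eighth column
    is the fixed point charge used by mechanical (MM) embedding.

    Returns
    -------
    (list of AtomParams, GlobalParams)
    """
    path = Path(path)
    if not path.is_file():
        raise ParameterFileError(f"parameter file not found: {path}")
    atoms = []
    header = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        if tokens[0] in _HEADER_KEYS:
            if atoms:
                raise ParameterFileError(
                    f"{path}:{lineno}: header line after atom records"
                )
            if len(tokens) % 2 != 0:
                raise ParameterFileError(
                    f"{path}:{lineno}: header needs key/value pairs"
                )
            for key, val in zip(tokens[::2], tokens[1::2]):
                if key not in _HEADER_KEYS:
                    raise ParameterFileError(
                        f"{path}:{lineno}: unknown header key {key!r}"
                    )
                try:
                    header[_HEADER_KEYS[key]] = float(val)
                except ValueError:
                    raise ParameterFileError(
                        f"{path}:{lineno}: bad value for {key!r}: {val!r}"
                    ) from None
            continue
        if len(tokens) not in (7, 8):
            raise ParameterFileError(
                f"{path}:{lineno}: expected 7 or 8 fields, got {len(tokens)}"
            )
        try:
            values = [float(t) for t in tokens[1:]]
        except ValueError:
            raise ParameterFileError(
                f"{path}:{lineno}: non-numeric field in {line!r}"
            ) from None
        q_mm = values[6] if len(values) == 7 else None
        try:
            atoms.append(
                AtomParams(
                    element=tokens[0],
                    q_core=values[0],
                    q_val=values[1],
                    s=values[2],
                    chi=values[3],
                    hardness_J=values[4],
                    k_Z=values[5],
                    q_mm=q_mm,
                )
            )
        except ValueError as exc:
            raise ParameterFileError(f"{path}:{lineno}: {exc}") from None
    if not atoms:
        raise ParameterFileError(f"{path}: no atom records")
    return atoms, GlobalParams(**header)


def write_parameter_file(
    path: Union[str, Path],
    atoms: Sequence[AtomParams],
    global_params: GlobalParams = GlobalParams(),
) -> None:
    """Write a parameter file in the dialect of :func:`read_parameter_file`."""
    lines = [
        "# EMLE parameter file: element q_core q_val s chi J k_Z [q_mm]",
        f"a_QEq {global_params.a_qeq!r} a_damp {global_params.a_damp!r} "
        f"thole_a {global_params.thole_a!r}",
    ]
    for p in atoms:
        rec = (
            f"{p.element:<3s} {p.q_core: .10f} {p.q_val: .10f} {p.s: .10f} "
            f"{p.chi: .10f} {p.hardness_J: .10f} {p.k_Z: .10f}"
        )
        if p.q_mm is not None:
            rec += f" {p.q_mm: .10f}"
        lines.append(rec)
    Path(path).write_text("\n".join(lines) + "\n")
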