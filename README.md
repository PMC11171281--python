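# emlekit

Electrostatic machine-learning embedding (EMLE) energies and gradients for
hybrid ML/MM molecular dynamics, with a drop-in "external QM engine"
server and a 2D umbrella-sampling/WHAM helper.

## The problem

Machine-learned potentials (MLPs) predict in-vacuo energies of a molecular
subsystem at near-QM accuracy, but they carry no electronic density, so
they cannot be polarized by an MM environment the way a QM region is in
electrostatically embedded QM/MM.  EMLE closes that gap with a
physics-based model of the subsystem's density and its response, built
from a handful of per-atom parameters derived from in-vacuo properties
(MBIS density partitioning).  The total energy is

    E = E_vac(ML coords) + E_EMLE(ML, MM) ,
    E_EMLE = E_static + E_ind ,

where the induction term already contains the polarization cost.

**Static term.**  Each ML atom is a core point charge q_core plus a
valence Slater shell ρ(r) ∝ q_val e^(−r/s).  The shell potential

    V(r) = (q/r) · (1 − e^(−r/s)(1 + r/2s))

is finite at the nucleus and reproduces charge penetration at short
range.  Total atomic charges respond to geometry through charge
equilibration (QEq): minimize Σᵢ (χᵢ qᵢ + ½ Jᵢ qᵢ²) + Σᵢ<ⱼ qᵢ qⱼ E^int(σᵢ,σⱼ,rᵢⱼ)
subject to Σ qᵢ = Q, with Gaussian-shielded Coulomb interactions of width
σᵢ = a_QEq·sᵢ.  E_static is the interaction of the MM point charges with
the resulting core + valence density.

**Induction term.**  Isotropic polarizabilities αᵢ = k_Z·Nᵢ·60 sᵢ³
(proportional to the MBIS atomic volume) enter a Thole induced-dipole
model: (diag(α⁻¹) + T) μ = E, with cubic-exponential damping in T and MM
fields screened at short range by the charge-penetration factor of a
Slater shell of width a_damp·s (a_damp = 2).  Then
E_ind = −½ μ·E ≤ 0.

Because the scheme needs only ML-atom positions plus MM charges and
positions — exactly what QM/MM codes hand to an external QM engine — it
can masquerade as "just another QM engine": emlekit ships a file-protocol
TCP server and client for that purpose.

## Worked example

```python
import numpy as np
from emlekit import MMEnvironment, ToyBackend, total_energy
from emlekit.fixtures import make_solute_fixture, make_charge_shell

ml = make_solute_fixture(5, seed=7)              # 5-atom synthetic solute
mm = make_charge_shell(12, radius=9.0, seed=8)   # 12-point-charge shell

res = total_energy(ml, mm, ToyBackend(), mode="emle_total")
print(f"E_vac      = {res.e_vac: .8f} hartree")
print(f"E_static   = {res.embedding.e_static: .8f} hartree")
print(f"E_ind      = {res.embedding.e_ind: .8f} hartree")
print(f"E_total    = {res.e_total: .8f} hartree")
print("QEq charges (e):", np.round(res.embedding.qeq_charges, 4))
```

prints

```
E_vac      =  0.48339172 hartree
E_static   = -0.01538856 hartree
E_ind      = -0.00090463 hartree
E_total    =  0.46709853 hartree
QEq charges (e): [-0.2179 -0.178  -0.2385 -0.1746 -0.1909]
```

The vacuum term comes from the bundled deterministic toy backend (any
callable mapping ML coordinates to energy + gradients plugs in the same
way).  The static embedding is stabilizing here because the equilibrated
charges (which sum exactly to the region's net charge, −1 e) interact
favourably with the surrounding shell; the induction term is negative by
construction.  `res.grad_ml` / `res.grad_mm` hold the analytic gradients
(hartree/bohr), exact derivatives of the printed energy including the
charge-response term of the QEq solve.

### Engine server

```bash
emlekit fixtures job/ --n-atoms 4 --n-charges 8 --seed 3  # synthetic job dir
emlekit serve --port 10101 &                              # long-running server
emlekit client job/ --port 10101                          # fake-QM-executable call
emlekit shutdown --port 10101
```

`emlekit run job/` evaluates the same job directly; server and direct
replies are byte-identical.  Reply files (`emle.engrad`, `emle.pcgrad`)
use energies in hartree and gradients in hartree/bohr; request files use
Å.  The umbrella/WHAM helper is available as `emlekit wham2d`.

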