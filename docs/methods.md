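# Methods

This note records the model equations as implemented, the numerical
choices behind them, what the synthetic fixtures do and do not emulate,
and the known limitations.

## Model

### Static electrostatics

The in-vacuo electronic density of the embedded (ML) region is a sum of
atomic densities: a core point charge `q_core` plus a spherical valence
Slater shell

    rho_val(r) = q_val / (8 pi s^3) * exp(-r / s),

with width `s` in bohr.  Integrating the density against the Coulomb
kernel gives the closed-form shell potential

    V(r) = (q/r) * (1 - exp(-r/s) * (1 + r/(2s))),

with V(0) = q/(2s) and V -> q/r as r -> infinity or s -> 0.  The static
embedding energy is the sum over (ML atom, MM site) pairs of the MM
charge times core-point plus shell potential.  Both the potential and the
Gauss-law field factor g(x) = 1 - e^(-x)(1 + x + x^2/2) switch to series
expansions below x = 1e-3 / 1e-2 respectively to avoid cancellation; the
crossover keeps relative error below ~1e-12.

The closed forms are pinned by an independent oracle that numerically
integrates the density itself (adaptive radial quadrature after the exact
angular reduction of 1/|r - r'| over a sphere, certified to 1e-9); the
oracle shares no formula code with the production path.

### Charge equilibration

Total atomic charges minimize

    E(q) = sum_i [chi_i q_i + 1/2 A_ii q_i^2] + sum_{i<j} q_i A_ij q_j,
    s.t. sum_i q_i = Q,

with Gaussian-shielded off-diagonal couplings.  Width convention: sigma
is the standard deviation of rho ∝ exp(-r^2 / 2 sigma^2), giving

    A_ij = erf(r_ij / sqrt(2 (sigma_i^2 + sigma_j^2))) / r_ij,
    A_ii = J_i + 1 / (sigma_i sqrt(pi)),

so the diagonal is exactly the r -> 0 limit of the off-diagonal coupling
when J_i = 0, and the matrix entries are continuous functions of
geometry by construction.  This convention is a package choice (the
normalization is not uniquely fixed by the compact textbook notation) and
is pinned against a numeric density-interaction oracle rather than
asserted as canonical.  sigma_i = a_QEq * s_i ties the shielding width to
the valence shell width.

The constrained quadratic program is solved exactly by one bordered
(KKT) linear solve; a condition number above 1e12 raises a named error
carrying the condition number.  This is appropriate for the intended
region sizes (up to a few hundred atoms); no iterative solver is needed.

How the QEq charge shift partitions between core and valence is a model
choice: the core charge is held fixed and the valence shell absorbs the
entire shift (q_val = q_total - q_core) at fixed width, on the grounds
that core electrons are inert in an MBIS-style partitioning.

### Induction

Polarizabilities are proportional to MBIS atomic volumes.  The volume is
taken as N * <r^3> of the normalized valence density — the third-radial-
moment convention of the MBIS literature — which evaluates to

    alpha = k_Z * N * 60 s^3,   N = -q_val.

Atoms with k_Z = 0 carry no dipole and are excluded from the response
matrix entirely (so a zero-polarizability run is bitwise identical to a
static-only run).

The induced dipoles solve (diag(1/alpha) + T) mu = E_screened.

* T uses the classical dipole tensor with Thole cubic exponential
  damping, lambda_3 = 1 - e^(-a u^3), lambda_5 = 1 - (1 + a u^3) e^(-a u^3),
  at scaled distance u = r / (alpha_i alpha_j)^(1/6).  The damping width
  `thole_a` defaults to 0.39, the standard value used with this
  exponential-3 form in polarizable force fields.
* The MM field at atom i is the bare Coulomb field times the
  enclosed-charge fraction of a Slater shell of width a_damp * s_i.  For
  a spherical screening density, multiplying by the enclosed-charge
  fraction and taking the negative radial derivative of the screened
  potential are the same operation (Gauss's law), so the two candidate
  readings of "damping by the atomic density" coincide.  a_damp defaults
  to 2 (the value established by grid search against DFT reference
  induction energies in the EMLE literature); a_damp = 0 disables
  screening, which is used by the textbook point-dipole cross-check.

The induction energy is E_ind = -1/2 mu . E, negative whenever the
response matrix is positive definite (true on all shipped fixtures; a
singular matrix raises a named error).

### Gradients

All gradients are analytic.  The induction gradient uses the variational
property of the half-form: dE_ind = -mu . dE + 1/2 mu dB mu, so no
dipole-response derivatives appear.  For the static term two paths exist:

* fast path: QEq charges treated as constants;
* exact path (default): an adjoint solve on the same KKT matrix adds the
  charge-response term, making the gradient the exact derivative of the
  energy (the property MD energy conservation needs).  QEq is an
  in-vacuo property, so this term touches ML atoms only.

`qeq_gradient_discrepancy` reports the magnitude of the neglected term of
the fast path.  All paths are verified against Richardson-extrapolated
central differences to ~1e-11 relative on random fixtures.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| q_core | e | per atom | core (nucleus + core electrons) charge |
| q_val | e | per atom | valence shell charge (negative) |
| s | bohr | per atom | valence Slater width |
| chi | hartree/e | per atom | electronegativity |
| J | hartree/e^2 | per atom | hardness (self-energy) |
| k_Z | — | per element | polarizability scaling |
| q_mm | e | optional | fixed charge for mechanical embedding |
| a_QEq | — | 1.0 | shielding width scale sigma = a_QEq s |
| a_damp | — | 2.0 | field-screening width scale |
| thole_a | — | 0.39 | Thole damping width |

The parameter file supports per-atom chi and J (they may be element
constants or per-atom predictions; the file format covers both).  The
a_QEq and thole_a defaults are artifact choices documented here, not
fitted values; a_damp = 2 is the literature value.  In production use all
per-atom parameters come from an upstream property predictor — training
such a predictor is outside this package's scope, and the shipped
per-element fixture table contains physically plausible magnitudes only.

## Embedding modes

`mechanical_mm` (fixed q_mm point charges, plain Coulomb),
`emle_static` (QEq + Slater static term), and `emle_total` (static +
induction).  An empty MM environment yields exactly the vacuum energy in
every mode.  No ordering between |static| and |total| embedding energies
is asserted anywhere: the model does not guarantee one.

## Engine interface

The file dialect (coords.xyz in Å; pointcharges.pc with a count header;
emle.engrad / emle.pcgrad replies in hartree and hartree/bohr) is this
package's own pinned simplification of the sander↔ORCA external-engine
exchange; the genuine byte layout is not reproduced, only the
information content.  Numbers are written with 16 significant digits so
identical requests produce byte-identical replies — the server path and
the direct library path share one code path and are byte-compared in the
tests.  The wire protocol (`<MSGTYPE> <length>\n` + UTF-8 payload; RUN /
PING / SHUTDOWN) favours debuggability; requests are served strictly
FIFO by a single-threaded accept loop, which is what makes multi-client
determinism trivial.  Link atoms / covalent ML–MM boundaries are not
supported: the embedded region is assumed to be a whole molecule.

## Umbrella sampling / WHAM

Windows restrain two periodic dihedrals with harmonic biases
(minimal-image wrapped, k in kcal/mol/rad^2; the production protocol uses
k = 100 and a 36 x 10-degree window grid per angle, 1296 windows).  WHAM
iterates the standard two equations on a square bin grid (default 72 bins
= 5-degree bins, matching half the production window spacing) until the
largest window-offset change falls below 1e-7 kcal/mol; non-convergence
raises an error carrying the last residual.  The temperature default
(300 K) and bin width are artifact choices.  Free energies are anchored
to min = 0 over populated bins; unpopulated bins are NaN.

Surface comparison (`fes_rmse`) restricts to bins populated in both
surfaces and below a 20 kcal/mol cutoff in the reference, and removes the
optimal constant offset by default (free energies are defined up to a
constant; the flag exposes the raw comparison).

The recovery check samples an analytic smooth torus potential
(amplitudes 1.6 / 1.2 / 0.6 kcal/mol — barriers a few kT at 300 K,
resolvable by modest sampling) with vectorized Metropolis walkers, one
per window, thinned 10x so samples are close to independent.  The desk-
scale study conditions are a 12 x 12 window grid at 30-degree spacing
with k = 15 kcal/mol/rad^2 (restraint width ~11 degrees, comparable to
the window spacing, mirroring the overlap regime of the production
protocol), 800 samples per window, and 24 x 24 bins.  The acceptance
threshold is three times an analytic error estimate: per-bin free-energy
variance (kT)^2 / n_eff with n_eff the expected bias-reweighted count
integrated exactly from the known biased Boltzmann densities.  Measured
RMSE sits at roughly half the 3x budget across seeds.

## What the synthetic fixtures do and do not show

Fixture solutes are random H/C/N/O clusters with a 1.5 bohr minimum
separation and table-driven parameters; charge shells place TIP3P-like
random charges on a sphere with an exactly constrained net charge.  They
exercise every code path (multi-element parameters, net-charged regions,
close contacts, empty environments) but are not conformers of any real
molecule, carry untrained parameters, and lack bulk-solvent structure.
Passing tests therefore demonstrate correctness of the implemented
mathematics — oracle equivalence, exact limits, exact gradients, protocol
determinism — not chemical accuracy against DFT references, which
requires trained parameters and reference calculations outside this
package's scope.

## Known limitations

* No periodic boundary conditions / Ewald: the model operates on the
  explicit charge list an MD engine supplies.
* No anisotropic polarizabilities, no permanent multipoles beyond the
  monopole density, no mutual MM polarization.
* Only the bundled toy in-vacuo backend ships; external MLP backends
  plug in through the callable interface but are not distributed.
* The exact-QEq gradient path costs one extra linear solve per call;
  for very large regions the fast path plus the discrepancy diagnostic
  may be preferred.
* WHAM only (no MBAR); bins are square and share edges across both
  angles.
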