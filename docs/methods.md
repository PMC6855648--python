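# Methods

This note documents the physics, conventions and numerical choices behind
`watermodels`: what is computed, under which assumptions, and where the
design was genuinely open.

## Multipole conventions

All internal computation uses the {e, Å, kcal/mol} unit system; Debye-based
quantities are converted at the boundary with 1 e·Å = 4.80320 D.  The
construction equations are only dimensionally consistent within a single
charge-length system, and this conversion reproduces the packaged parameter
tables to all printed digits (one tabulated value, the gas-exp 4-point
hydrogen charge, differs by one unit in the fourth decimal from the exact
solution of the constraint system; the package returns the exact value).

In the canonical molecular frame (C2 axis = z, plane = yz, oxygen at the
origin) the traceless quadrupole tensor of a C2v charge set is diagonal,
`Q = diag(−Q_t − Q_0/2, Q_t − Q_0/2, Q_0)`, and the z-slice of the traceless
octupole tensor is `diag(−Ω_t − Ω_0/2, Ω_t − Ω_0/2, Ω_0)`; the scalars are
read off as `Q_t = (Q_yy − Q_xx)/2`, `Q_0 = Q_zz`, `Ω_0 = O_zzz`,
`Ω_t = O_yyz + Ω_0/2`.  `moments_from_charges` computes only the needed
components; the test suite checks it against a brute-force full-tensor
oracle on random C2v layouts to 1e-10.

Sign convention: models are built with the hydrogens at positive z, so
μ ≥ 0.  Reported dipoles are magnitudes.

## Rigid-model construction

The three reference multipole sets (gas-phase experimental, gas-phase QM,
liquid-phase MP2/4MM) ship as packaged CSV fixtures; the experimental set
lacks measured octupoles and borrows the QM ones, as in the original
parameterization protocol.  Constructions:

* **3-point** — closed form fitting (μ, Q_t, Q_0); octupoles are residuals.
* **4-point** — the four-constraint system {μ = 2q(z2−z1),
  Q_t = (3/2)q·y1², Q_0 = q(2z2² − y1² − 2z1²), O_yyz = Ω_t − Ω_0/2} reduces
  to a quadratic in d = z2 − z1 once s = z1 + z2 = (2Q_t + 3Q_0)/(3μ) is
  eliminated.  Root selection: q > 0, y1 > 0, z2 > z1 and z1 ≥ 0 (the extra
  point lies between the oxygen and the hydrogen plane); if two roots
  qualify the compact one (largest q) is taken — the other root places the
  extra point far outside the molecule.  A `method="numeric"` path solves
  the same system with a generic root finder; both agree to 1e-8 and the
  quadratic is authoritative.
* **5-point** — with A = 2Q_t/3q, d = μ/2q, C = 2Ω_t/5q the axis offsets
  follow from s = z1 + z2 = (2C + d·Q_0/q)/(A + 2d²) and
  x1² ± y1² from A and Q_0/q − 2sd.  The hydrogen charge is chosen by
  exhaustive search on (0, 3] e with step 1e-4 e minimizing |Ω_0(model) −
  Ω_0(ref)|, followed by bounded golden-section refinement to 1e-7 e.  The
  grid step is far below the four printed decimals of the tabulated charges;
  candidates with non-real coordinates are skipped.

For n = 4, 5 the oxygen is a chargeless Lennard-Jones-only site at the
origin; for n = 3 it carries −2q.

## Drude oscillator

A massless particle of charge Q_D is tethered to the oxygen with an
isotropic virtual bond, equilibrium length 0, energy

    U(d) = k d²     (restoring force 2 k d),

the AMBER bond-energy convention, with k = 1000 kcal/mol/Å² throughout.
The charge label follows Q_D = √(α k)/18.2223 e, where α (Å³) is the
nominal polarizability parameter of the published tables.  Note that the
true linear response of this oscillator is α_mech = C·Q_D²/(2k) ≈ α/2
(C = 332.0637); `DrudeSpec` exposes both.  This convention was adopted
because it is the only one that reproduces the published polarizable-model
results (dimer dipole near 2.68 D, angle error near 3.2°, unconstrained
r(OO) near 2.91 Å with the tabulated σ); the ½kd² convention produces a
qualitatively different, collapse-dominated surface.  The induced-dipole
invariant in the test suite is asserted against α_mech.

The oxygen charge becomes −2q − Q_D so oxygen + Drude carry the base's −2q;
with zero displacement the polarizable molecule is electrostatically
identical to its rigid base.  The Drude has no Coulomb interaction with any
site of its own molecule; all intermolecular pairs interact.  Displacements
are relaxed self-consistently (Gauss–Seidel fixed point d = Q_D·E/(2k),
warm-started, tolerance 1e-13 Å) before every pose energy is reported; the
rigid-body gradient is then exact at fixed displacements by the envelope
condition.

A point Drude on a linear spring is unbounded below at close contact
(polarization catastrophe).  Poses whose relaxation diverges, or whose
relaxed displacement exceeds `max_drude_disp` (default 0.6 Å, far outside
the ≤ 0.07 Å seen in the physical basin), are flagged collapsed and
excluded; they appear in the minimization diagnostics.  No displacement cap
or Thole screening is applied inside the physical basin.

## Dimer energetics and minimization

Two identical molecules; molecule 1 clamped in the canonical frame,
molecule 2 parameterized by a quaternion (normalized internally, so the
gauge direction has zero gradient) and a translation.  Energy is the exact
pairwise intermolecular Coulomb sum plus one O–O Lennard-Jones term
(ε tabulated in kJ/mol, converted by 4.184) plus the Drude springs — no
cutoffs, no periodicity, no intramolecular Coulomb.  Gradients are analytic
(pairwise forces chained through the quaternion derivative); L-BFGS-B with
ftol 1e-14 / gtol 1e-10 typically reaches projected-gradient norms below
1e-8, and the returned state's gradient norm is checked against the `tol`
argument (default 1e-6).  An optional constraint holds r(OO) fixed by
reparameterizing the translation as a direction.

**Stationary-state structure.**  These optimal point-charge layouts place
the charges far from the nuclei, and their dimer surfaces are not
single-minimum.  Three families of stationary states matter:

* the **single-donor hydrogen-bonded** (Cs) structure the reference dimer
  targets describe;
* a **cyclic doubly hydrogen-bonded** (C2h-like) structure with total dipole
  exactly zero, which lies *below* the Cs structure for the 3-point-geometry
  models (rigid 3-point and both polarizable models) — for the 4- and
  5-point models the Cs structure is the global minimum;
* for polarizable models, the collapsed (catastrophe) region.

For the 3-point-geometry models the Cs structure is in fact a first-order
saddle of the full six-dimensional surface: it is the minimum within the
Cs-symmetric subspace, and unstable along the acceptor-spin direction
toward the cyclic state.  The parameterization protocol is nevertheless
defined on the Cs structure (its dipole criterion is meaningless at the
dipole-cancelling cyclic state), so `minimize_dimer` defaults to
`basin="hbond"`: among the restart results it returns the lowest-energy
state with the reference topology — a single donor (the two closest
H···O(other) distances differing by ≥ 0.2 Å) whose donor molecular plane
contains the O–O line while the acceptor's does not.  `basin="global"`
returns the lowest valid state regardless.  Half the restarts start from
hydrogen-bonded templates placed exactly on the Cs symmetry plane
(randomized donor tilt 25–85°, acceptor tilt 15–85°, O–O distance); on the
plane the symmetry-breaking gradient component vanishes identically, so
local minimization converges to the Cs stationary state even where it is
transversally unstable.  The other half are uniform random poses (rotation
uniform over SO(3), O–O distance uniform over 2.5–4.0 Å), which locate the
cyclic and collapsed states.  Per-restart energies, basin classifications
and Drude diagnostics are returned in `DimerState.diagnostics`; when the
selected basin is not the lowest one found, the lower energy is reported
there.

**Geometry descriptors.**  The donor is the molecule owning the hydrogen
closest to the other oxygen; θ (donor) and φ (acceptor) are the angles
between each molecule's C2 axis (negative-charge center toward the hydrogen
midpoint) and the donor-to-acceptor O–O direction.  The total dipole is the
magnitude of Σqᵢrᵢ over all sites, Drude displacements included (the dimer
is neutral, so it is origin-independent).  The angle error is
|θ − 57.9°| + |φ − 55.6°|.

**Evaluation modes.**  Following the published two-stage protocol: O–O
distances and dimer dipoles (the LJ fit and the μ/α optimization criteria)
are measured on the *unconstrained* minimized dimer, whose r(OO) the σ fit
pins to 2.91 Å; angle evaluations hold r(OO) *fixed* at 2.91 Å.

## Optimization loops

* `fit_lj_sigma` — bisection on σ until the minimized r(OO) is within
  1e-3 Å of 2.91 Å.  The bracket is grown outward from σ ≈ r_ref/0.88 (the
  empirical r(OO)/σ ratio of these oxygen-LJ dimers) in 0.15 Å steps within
  [2.5, 4.5] Å; the minimized r(OO) is asserted monotone in σ over the
  final bracket.  Only σ is fitted: a single target distance determines a
  single LJ parameter, so ε is an input (the tabulated value of the row
  being reproduced).
* `optimize_mu` — bisection on the monomer dipole until the dimer total
  dipole is within 0.1% (relative) of 2.68 D, rebuilding the model and
  re-fitting σ at every trial.  Default brackets per n (3: 1.7–2.3 D,
  4: 2.05–2.7 D, 5: 2.1–2.8 D) — the 4-/5-point constructions have no real
  solution below a minimum dipole set by the octupole constraint.
* `optimize_alpha` — same criterion, varying α with the rigid base frozen;
  σ either fixed (reproducing tabulated runs) or re-fitted per trial.
* `scan_mu_alpha` — the joint grid with the combined error
  angle_error/180° + |dipole − 2.68|/2.68 per cell.  The joint problem is
  under-determined (the feasible set is a band); the full surface, the
  feasible subset and the minimum-combined-error cell are all returned, and
  build failures flag cells rather than aborting.

Root-finding stops as soon as the stated criterion is met; every converged
run satisfies its own criterion when re-evaluated from scratch, and reports
carry the seed, history and tolerances needed to reproduce them bit for
bit.  Inner loops default to 8 restarts per minimization; final evaluations
use 32.  Multi-start results are seed-independent to well below 1e-6
kcal/mol.

## Synthetic references

`generate_synthetic_reference` draws multipole sets uniformly from ranges
bracketing the three packaged sets (μ 1.6–2.8 D, Q_t 2.2–3.2 D·Å, Q_0
0.02–0.30 D·Å, Ω_t 1.6–2.3 D·Å², Ω_0 −2.0 to −1.0 D·Å²), rejection-sampling
until both the 3- and 4-point constructions succeed.  It emulates only the
monomer-moment inputs of the pipeline — not ab initio noise, conformational
flexibility or liquid-phase observables — so property tests built on it
demonstrate algebraic correctness of the constructions, not accuracy of any
model for real water.

## Known limitations

* The reported hydrogen-bonded state is, for 3-point-geometry models, a
  symmetric saddle rather than a true minimum of the model's surface; the
  package reports this faithfully in the diagnostics rather than hiding it.
* With the published rounded parameters the polarizable dimer dipole is
  reproduced to ~0.2–0.4%, not to the 0.1% used as the original optimization
  stopping rule; the rigid models reproduce their criteria to ≤ 0.15%.
* Polarizability is isotropic and unscreened; hydrogens carry no LJ; no
  liquid-phase observables are computed.
* The σ fit assumes a monotone r(OO)–σ relation, valid over the physical
  bracket but not in the collision regime at very small σ (the bracket
  search avoids it).
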