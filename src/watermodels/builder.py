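"""Closed-form construction of rigid C2v n-point water models (n = 3, 4, 5).

Each model is an optimal point-charge approximation of a reference multipole
set: the site layout is constrained to C2v symmetry (Fig conventions: C2 axis
= z, hydrogens at (0, ±y1, z2)) and charges/coordinates are solved so the
leading moments are matched exactly.

* n = 3: sites {H(+q), H(+q), O(-2q at origin)}.  μ, Qt, Q0 are fitted
  exactly (z1 = 0 imposed); octupoles are unconstrained residuals.
* n = 4: the -2q charge moves to an extra point at (0, 0, z1); the oxygen is
  a chargeless LJ-only site at the origin.  μ, Qt, Q0 and the octupole
  combination O_yyz = Ωt - Ω0/2 are fitted exactly.
* n = 5: two extra points (-q each) at (±x1, 0, z1); μ, Qt, Q0, Ωt are fitted
  exactly for any hydrogen charge q, and q is chosen by exhaustive grid
  search (plus golden-section refinement) to minimize the Ω0 residual.

All algebra runs in e·Å^n units; the public interface speaks Debye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import fsolve, minimize_scalar

from .constants import DEBYE_PER_EA
from .multipoles import ChargeSite, MultipoleSet


@dataclass(frozen=True)
class ModelGeometry:
    """A rigid C2v point-charge water model.

    Coordinates are Å in the canonical frame; ``q`` is the hydrogen charge in
    e.  ``z1`` is the extra-point height (0 and unused for n = 3); ``x1`` is
    the extra-point off-axis offset (n = 5 only).  LJ parameters live on the
    oxygen; ``lj_epsilon`` is stored in kJ/mol as customarily tabulated.
    """

    n_points: int
    q: float
    y1: float
    z2: float
    z1: float = 0.0
    x1: float = 0.0
    lj_sigma: float = float("nan")
    lj_epsilon: float = float("nan")
    name: str = ""

    def __post_init__(self):
        if self.n_points not in (3, 4, 5):
            raise ValueError(f"n_points must be 3, 4 or 5, got {self.n_points}")
        for label in ("q", "y1", "z2", "z1", "x1"):
            if not math.isfinite(getattr(self, label)):
                raise ValueError(f"{label} must be finite, got {getattr(self, label)}")
        if self.q <= 0:
            raise ValueError(f"hydrogen charge must be positive, got {self.q}")
        if self.y1 <= 0:
            raise ValueError(f"y1 must be positive, got {self.y1}")
        if self.n_points == 3 and self.z1 != 0.0:
            raise ValueError("3-point models have no extra point: z1 must be 0")
        if self.n_points != 5 and self.x1 != 0.0:
            raise ValueError("x1 is only meaningful for 5-point models")
        if self.n_points == 5 and self.x1 < 0:
            raise ValueError(f"x1 must be >= 0, got {self.x1}")

    def with_lj(self, sigma: float, epsilon_kj: float) -> "ModelGeometry":
        """Return a copy with LJ parameters (σ in Å, ε in kJ/mol) attached."""
        return replace(self, lj_sigma=sigma, lj_epsilon=epsilon_kj)

    def to_sites(self) -> list[ChargeSite]:
        """Materialize the canonical-frame charge sites.

        The oxygen site is always present at the origin (it carries the LJ
        center); for n = 4, 5 it is chargeless.
        """
        q, y1, z1, z2, x1 = self.q, self.y1, self.z1, self.z2, self.x1
        sites = [
            ChargeSite((0.0, y1, z2), q, "hydrogen"),
            ChargeSite((0.0, -y1, z2), q, "hydrogen"),
        ]
        if self.n_points == 3:
            sites.append(ChargeSite((0.0, 0.0, 0.0), -2.0 * q, "oxygen"))
        elif self.n_points == 4:
            sites.append(ChargeSite((0.0, 0.0, 0.0), 0.0, "oxygen"))
            sites.append(ChargeSite((0.0, 0.0, z1), -2.0 * q, "extra_point"))
        else:
            sites.append(ChargeSite((0.0, 0.0, 0.0), 0.0, "oxygen"))
            sites.append(ChargeSite((x1, 0.0, z1), -q, "extra_point"))
            sites.append(ChargeSite((-x1, 0.0, z1), -q, "extra_point"))
        return sites

    @property
    def mu(self) -> float:
        """Monomer dipole moment of the model, in D."""
        return 2.0 * self.q * (self.z2 - self.z1) * DEBYE_PER_EA


def build_3point(ref: MultipoleSet, mu: float) -> ModelGeometry:
    """Build the 3-point model fitting (μ, Qt, Q0) exactly.

    ``mu`` is the monomer dipole in D (the free parameter of the outer dimer
    optimization); Qt and Q0 come from ``ref``.  Closed form in e·Å units:

        q  = 3 μ² / (2 (2 Qt + 3 Q0)),   z2 = μ / (2 q),   y1 = sqrt(2 Qt / (3 q)).
    """
    if not (mu > 0):
        raise ValueError(f"monomer dipole must be positive, got {mu} D")
    d = DEBYE_PER_EA
    mu_a, qt, q0 = mu / d, ref.Qt / d, ref.Q0 / d
    denom = 2.0 * qt + 3.0 * q0
    if denom <= 0:
        raise ValueError(f"quadrupole/charge inconsistency: 2*Qt + 3*Q0 = {denom * d:.4f} D·Å <= 0")
    q = 3.0 * mu_a**2 / (2.0 * denom)
    z2 = mu_a / (2.0 * q)
    rad = 2.0 * qt / (3.0 * q)
    if rad <= 0:
        raise ValueError("quadrupole/charge inconsistency: negative discriminand for y1")
    return ModelGeometry(3, q=q, y1=math.sqrt(rad), z2=z2, name=ref.name)


def _solve_4point(mu_a: float, qt: float, q0: float, t_yyz: float):
    """Roots (q, y1, z1, z2) of the 4-constraint system, e·Å units.

    With s = z1 + z2 fixed by (μ, Qt, Q0) and d = z2 - z1, the octupole
    constraint O_yyz = t_yyz reduces to a quadratic in d:

        (μ/8) d² - (4 Qt/3) d + [t_yyz - (4 Qt/3) s + (3 μ/8) s²] = 0.
    """
    s = (2.0 * qt + 3.0 * q0) / (3.0 * mu_a)
    a = mu_a / 8.0
    b = -(4.0 * qt / 3.0)
    c = t_yyz - (4.0 * qt / 3.0) * s + (3.0 * mu_a / 8.0) * s * s
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return []
    roots = []
    for d in ((-b + math.sqrt(disc)) / (2.0 * a), (-b - math.sqrt(disc)) / (2.0 * a)):
        if d <= 0:
            continue
        q = mu_a / (2.0 * d)
        z1, z2 = (s - d) / 2.0, (s + d) / 2.0
        rad = 2.0 * qt / (3.0 * q)
        if rad <= 0:
            continue
        roots.append((q, math.sqrt(rad), z1, z2))
    return roots


def build_4point(ref: MultipoleSet, mu: float, *, method: str = "closed") -> ModelGeometry:
    """Build the 4-point model fitting (μ, Qt, Q0, Ωt - Ω0/2) exactly.

    The fitted octupole combination is O_yyz = Ωt - Ω0/2; Ω0 itself is an
    unconstrained residual.  ``method`` selects the closed-form quadratic
    (``"closed"``) or an equivalent numerical solve of the same 4-equation
    system (``"numeric"``); both agree to well below printed precision.

    Root selection: q > 0, y1 > 0, z2 > z1 and z1 >= 0 (the extra point lies
    between the oxygen and the hydrogen plane); with several candidates the
    most compact one (largest q) is returned.
    """
    if not (mu > 0):
        raise ValueError(f"monomer dipole must be positive, got {mu} D")
    if not ref.has_octupoles:
        raise ValueError(f"reference {ref.name!r} has no octupole moments")
    d = DEBYE_PER_EA
    mu_a, qt, q0 = mu / d, ref.Qt / d, ref.Q0 / d
    t_yyz = (ref.Omega_t - ref.Omega_0 / 2.0) / d

    roots = _solve_4point(mu_a, qt, q0, t_yyz)
    roots = [r for r in roots if r[2] >= 0.0]
    if not roots:
        raise ValueError(
            "no real 4-point solution with q > 0 and 0 <= z1 < z2 for "
            f"(mu={mu} D, Qt={ref.Qt}, Q0={ref.Q0}, Omega_t-Omega_0/2={ref.Omega_t - ref.Omega_0 / 2.0} D·Å²)"
        )
    q, y1, z1, z2 = max(roots, key=lambda r: r[0])

    if method == "numeric":
        def system(x):
            qq, yy, za, zb = x
            return [
                2.0 * qq * (zb - za) - mu_a,
                1.5 * qq * yy * yy - qt,
                qq * (2.0 * zb * zb - yy * yy - 2.0 * za * za) - q0,
                qq * (4.0 * yy * yy * zb - zb**3 + za**3) - t_yyz,
            ]

        sol, info, ok, msg = fsolve(system, [q, y1, z1, z2], full_output=True)
        if ok != 1:
            raise ValueError(f"numeric 4-point solve failed: {msg}")
        q, y1, z1, z2 = sol
    elif method != "closed":
        raise ValueError(f"unknown method {method!r}")

    return ModelGeometry(4, q=q, y1=y1, z2=z2, z1=z1, name=ref.name)


def _coords_5point(q: float, mu_a: float, qt: float, q0: float, ot: float):
    """Coordinates (x1, y1, z1, z2) fitting (μ, Qt, Q0, Ωt) exactly at charge q.

    Derived from the 5-point moment expressions: with A = 2Qt/(3q),
    d = μ/(2q), C = 2Ωt/(5q) and s = z1 + z2,

        s = (2C + d Q0/q) / (A + 2 d²),
        x1² - y1² = Q0/q - 2 s d,   x1² + y1² = A.

    Returns None when the implied x1², y1² are not real-nonnegative.
    """
    a_sum = 2.0 * qt / (3.0 * q)
    dlt = mu_a / (2.0 * q)
    c_oct = 2.0 * ot / (5.0 * q)
    s = (2.0 * c_oct + dlt * q0 / q) / (a_sum + 2.0 * dlt * dlt)
    b_dif = q0 / q - 2.0 * s * dlt
    u = (a_sum + b_dif) / 2.0  # x1^2
    v = (a_sum - b_dif) / 2.0  # y1^2
    if u < 0 or v <= 0:
        return None
    return math.sqrt(u), math.sqrt(v), (s - dlt) / 2.0, (s + dlt) / 2.0


def _omega0_5point(q, x1, y1, z1, z2):
    return q * (3.0 * x1**2 * z1 - 3.0 * y1**2 * z2 - 2.0 * z1**3 + 2.0 * z2**3)


def build_5point(
    ref: MultipoleSet,
    mu: float,
    *,
    q_max: float = 3.0,
    q_step: float = 1e-4,
    refine_tol: float = 1e-7,
) -> ModelGeometry:
    """Build the 5-point model fitting (μ, Qt, Q0, Ωt) exactly.

    For every candidate hydrogen charge q on the grid (0, q_max] with step
    ``q_step``, the coordinates follow from the closed forms; the returned q
    minimizes the axial-octupole residual |Ω0(model) - Ω0(ref)|, with a final
    bounded golden-section refinement to ``refine_tol`` (in e).
    Candidates with non-real coordinates are skipped.
    """
    if not (mu > 0):
        raise ValueError(f"monomer dipole must be positive, got {mu} D")
    if not ref.has_octupoles:
        raise ValueError(f"reference {ref.name!r} has no octupole moments")
    d = DEBYE_PER_EA
    mu_a, qt, q0 = mu / d, ref.Qt / d, ref.Q0 / d
    ot, o0 = ref.Omega_t / d, ref.Omega_0 / d

    def residual(q):
        c = _coords_5point(q, mu_a, qt, q0, ot)
        if c is None:
            return math.inf
        return abs(_omega0_5point(q, *c) - o0)

    grid = np.arange(q_step, q_max + q_step / 2.0, q_step)
    errs = np.array([residual(q) for q in grid])
    if not np.any(np.isfinite(errs)):
        raise ValueError(
            f"no feasible 5-point charge in (0, {q_max}] e for reference {ref.name!r} at mu={mu} D"
        )
    i = int(np.argmin(errs))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(residual, bounds=(lo, hi), method="bounded",
                          options={"xatol": refine_tol})
    q = float(res.x) if res.fun <= errs[i] else float(grid[i])
    x1, y1, z1, z2 = _coords_5point(q, mu_a, qt, q0, ot)
    return ModelGeometry(5, q=q, y1=y1, z2=z2, z1=z1, x1=x1, name=ref.name)


def build_rigid(ref: MultipoleSet, mu: float, n_points: int, **kwargs) -> ModelGeometry:
    """Dispatch to the n-point constructor."""
    if n_points == 3:
        return build_3point(ref, mu)
    if n_points == 4:
        return build_4point(ref, mu, **kwargs)
    if n_points == 5:
        return build_5point(ref, mu, **kwargs)
    raise ValueError(f"n_points must be 3, 4 or 5, got {n_points}")
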