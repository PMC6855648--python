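"""Water-dimer energetics: energy, analytic gradients, global minimization
and geometry descriptors.

The dimer is two identical model molecules.  Molecule 1 is clamped in the
canonical frame (oxygen at the origin, C2 axis along z); molecule 2 carries a
rigid-body pose (unit quaternion + translation), which removes the six global
degrees of freedom.  The energy is the exact pairwise sum

    E = sum_{i in mol1, j in mol2} C q_i q_j / r_ij        (Coulomb, C = 332.0637)
      + 4 eps [ (sigma/r_OO)^12 - (sigma/r_OO)^6 ]         (single O-O LJ site)
      + sum_m  k |d_m|^2                                   (Drude virtual bonds)

with no intramolecular Coulomb, no cutoffs and no periodicity.  Drude
particles are massless: for every rigid pose their displacements are relaxed
self-consistently (adiabatic separation) before the pose energy is reported,
which makes the outer objective smooth and lets the rigid-body gradient be
evaluated at fixed displacements (envelope condition: the inner force balance
2 k d = Q_D E_local zeroes the cross term).

A point Drude on a linear spring has no lower energy bound: at close contact
the induced dipole can grow without limit (polarization catastrophe), which
shows up as a spurious collapsed basin well inside the LJ wall.  Restarts
whose relaxation diverges, or whose relaxed displacement exceeds
``max_drude_disp``, are flagged as collapsed and excluded from the returned
minimum; they are reported in the state's diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Union

import numpy as np
from scipy.optimize import minimize

from .constants import COULOMB_KCAL, DEBYE_PER_EA, KJ_PER_KCAL
from .builder import ModelGeometry
from .drude import PolarizableModel

Model = Union[ModelGeometry, PolarizableModel]

_EZ = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# internal site-system representation


class _System:
    """Canonical-frame site arrays for one molecule of the model."""

    def __init__(self, model: Model):
        if isinstance(model, PolarizableModel):
            sites = model.to_sites()[:3]  # H, H, O; Drude handled separately
            self.drude_q = model.spec.q_drude
            self.drude_k = model.spec.k
            self.polarizable = self.drude_q != 0.0
            sigma, eps = model.lj_sigma, model.lj_epsilon
        else:
            sites = model.to_sites()
            self.drude_q = 0.0
            self.drude_k = math.nan
            self.polarizable = False
            sigma, eps = model.lj_sigma, model.lj_epsilon
        self.pos = np.array([s.position for s in sites], dtype=float)
        self.chg = np.array([s.charge for s in sites], dtype=float)
        self.kinds = [s.kind for s in sites]
        self.iO = self.kinds.index("oxygen")
        self.h_idx = [i for i, k in enumerate(self.kinds) if k == "hydrogen"]
        if not (math.isfinite(sigma) and math.isfinite(eps)):
            raise ValueError("model has no LJ parameters attached (sigma/epsilon)")
        self.sigma = float(sigma)
        self.eps_kcal = float(eps) / KJ_PER_KCAL


def _quat_normalize(q):
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q)


def _quat_matrix(p):
    """Rotation matrix from a unit quaternion (x, y, z, w)."""
    x, y, z, w = p
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _matrix_to_quat(R):
    from scipy.spatial.transform import Rotation
    return Rotation.from_matrix(R).as_quat()


def _quat_chain(G, V, p):
    """Gradient wrt the unit quaternion p of E(R(p) V) given dE/d(R V) = G.

    G, V are (n, 3); uses R v = (w² - u·u) v + 2 (u·v) u + 2 w (u × v).
    """
    u, w = p[:3], p[3]
    a = float(np.sum(G * V))
    gu = G @ u
    vu = V @ u
    cross = np.sum(np.cross(V, G), axis=0)
    de_du = -2.0 * a * u + 2.0 * (V.T @ gu) + 2.0 * (G.T @ vu) + 2.0 * w * cross
    de_dw = 2.0 * w * a + 2.0 * float(u @ cross)
    return np.concatenate([de_du, [de_dw]])


# ---------------------------------------------------------------------------
# raw pair kernel (used by the state-based API, file re-evaluation and tests)


def coulomb_lj_energy(pos1, chg1, iO1, pos2, chg2, iO2, sigma, eps_kcal):
    """Intermolecular Coulomb + O-O LJ energy of two explicit site sets
    (positions Å, charges e, eps already in kcal/mol).  Raises on overlapping
    sites (r < 1e-6 Å)."""
    pos1 = np.asarray(pos1, float)
    pos2 = np.asarray(pos2, float)
    chg1 = np.asarray(chg1, float)
    chg2 = np.asarray(chg2, float)
    diff = pos1[:, None, :] - pos2[None, :, :]
    r = np.linalg.norm(diff, axis=2)
    if np.min(r) < 1e-6:
        i, j = np.unravel_index(int(np.argmin(r)), r.shape)
        raise ValueError(f"overlapping sites: |r1[{i}] - r2[{j}]| = {np.min(r):.2e} Å < 1e-6 Å")
    e = COULOMB_KCAL * float(np.sum(np.outer(chg1, chg2) / r))
    sr6 = (sigma / r[iO1, iO2]) ** 6
    e += 4.0 * eps_kcal * (sr6 * sr6 - sr6)
    return e


def _pair_energy_grad2(pos1, chg1, iO1, pos2, chg2, iO2, sigma, eps_kcal):
    """Energy plus dE/d(pos2_j) for every site j of molecule 2."""
    diff = pos2[None, :, :] - pos1[:, None, :]  # (n1, n2, 3)
    r = np.linalg.norm(diff, axis=2)
    qq = np.outer(chg1, chg2)
    inv_r = 1.0 / r
    e = COULOMB_KCAL * float(np.sum(qq * inv_r))
    # dE/dpos2_j = -C sum_i q_i q_j (pos2_j - pos1_i) / r^3
    g2 = -COULOMB_KCAL * np.einsum("ij,ijk->jk", qq * inv_r**3, diff)
    roo = r[iO1, iO2]
    sr6 = (sigma / roo) ** 6
    e += 4.0 * eps_kcal * (sr6 * sr6 - sr6)
    dlj = 4.0 * eps_kcal * (-12.0 * sr6 * sr6 + 6.0 * sr6) / roo
    g2[iO2] += dlj * diff[iO1, iO2] / roo
    return e, g2


def _field_at(point, pos, chg):
    """Electric field (kcal/mol/e/Å) at ``point`` from charges ``pos, chg``."""
    dv = point - pos
    r3 = np.sum(dv * dv, axis=1) ** 1.5
    return COULOMB_KCAL * np.sum((chg / r3)[:, None] * dv, axis=0)


# ---------------------------------------------------------------------------
# public state containers


@dataclass
class DimerState:
    """Rigid-body pose of molecule 2 plus (for polarizable models) the two
    global Drude displacement vectors, and the energy of that configuration."""

    quaternion: np.ndarray  # unit, scalar-last (x, y, z, w)
    translation: np.ndarray  # Å
    drude_disp: Optional[np.ndarray] = None  # (2, 3) Å
    energy: float = float("nan")  # kcal/mol
    diagnostics: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.quaternion = np.asarray(self.quaternion, float)
        self.translation = np.asarray(self.translation, float)
        if abs(np.linalg.norm(self.quaternion) - 1.0) > 1e-10:
            raise ValueError("quaternion must be unit to 1e-10")
        if self.drude_disp is not None:
            self.drude_disp = np.asarray(self.drude_disp, float).reshape(2, 3)

    @property
    def rotation_matrix(self) -> np.ndarray:
        return _quat_matrix(self.quaternion)


@dataclass(frozen=True)
class DimerGeometry:
    """Descriptors of a dimer configuration.

    theta: angle (deg) between the hydrogen-bond donor's C2 axis and the
    donor-to-acceptor O-O direction; phi: same for the acceptor.  The C2 axis
    points from the negative-charge center toward the hydrogen midpoint.
    ``angle_error`` is |theta - theta0| + |phi - phi0| against the reference
    dimer angles (defaults 57.9 and 55.6 deg).
    """

    r_oo: float
    theta: float
    phi: float
    total_dipole: float
    angle_error: float

    def __post_init__(self):
        if not (self.r_oo > 0):
            raise ValueError("r_oo must be positive")
        if not (0.0 <= self.theta <= 180.0 and 0.0 <= self.phi <= 180.0):
            raise ValueError("angles must lie in [0, 180] degrees")


# ---------------------------------------------------------------------------
# energy evaluation at a given state


def _assemble(system: _System, state: DimerState):
    """Positions/charges of both molecules (Drude rows appended last)."""
    R = _quat_matrix(_quat_normalize(state.quaternion))
    pos1 = system.pos.copy()
    chg1 = system.chg.copy()
    pos2 = system.pos @ R.T + state.translation
    chg2 = system.chg.copy()
    if system.polarizable:
        if state.drude_disp is None:
            disp = np.zeros((2, 3))
        else:
            disp = state.drude_disp
        pos1 = np.vstack([pos1, pos1[system.iO] + disp[0]])
        pos2 = np.vstack([pos2, pos2[system.iO] + disp[1]])
        chg1 = np.append(chg1, system.drude_q)
        chg2 = np.append(chg2, system.drude_q)
    return pos1, chg1, pos2, chg2


def dimer_energy(model: Model, state: DimerState) -> float:
    """Energy (kcal/mol) of the dimer at the given state.

    Drude displacements are taken from the state as-is (use
    :func:`minimize_dimer` or :func:`relax_drude` to relax them).
    """
    system = _System(model)
    pos1, chg1, pos2, chg2 = _assemble(system, state)
    e = coulomb_lj_energy(pos1, chg1, system.iO, pos2, chg2, system.iO,
                          system.sigma, system.eps_kcal)
    if system.polarizable:
        disp = state.drude_disp if state.drude_disp is not None else np.zeros((2, 3))
        e += system.drude_k * float(np.sum(disp * disp))
    return e


# ---------------------------------------------------------------------------
# Drude self-consistent relaxation


def _relax_drude(system: _System, pos1, pos2, d1, d2, *, tol=1e-13, maxit=500):
    """Self-consistent massless-Drude displacements (Gauss-Seidel fixed
    point d = (Q_D/k) E_ext).  Returns (d1, d2, converged)."""
    qd, k = system.drude_q, system.drude_k
    c = qd / (2.0 * k)  # force balance: 2 k d = Q_D E  (U = k d^2)
    a1 = pos1[system.iO]
    a2 = pos2[system.iO]
    chg = system.chg
    for _ in range(maxit):
        e1 = _field_at(a1 + d1, pos2, chg) + COULOMB_KCAL * qd * _unit_over_r3(a1 + d1, a2 + d2)
        n1 = c * e1
        e2 = _field_at(a2 + d2, pos1, chg) + COULOMB_KCAL * qd * _unit_over_r3(a2 + d2, a1 + n1)
        n2 = c * e2
        delta = max(float(np.max(np.abs(n1 - d1))), float(np.max(np.abs(n2 - d2))))
        d1, d2 = n1, n2
        if delta < tol:
            return d1, d2, True
        if not np.all(np.isfinite(d1)) or not np.all(np.isfinite(d2)) or delta > 1e3:
            return d1, d2, False
    return d1, d2, False


def _unit_over_r3(p, q):
    dv = p - q
    return dv / float(np.sum(dv * dv)) ** 1.5


def relax_drude(model: PolarizableModel, state: DimerState, *, tol: float = 1e-13) -> DimerState:
    """Return a copy of ``state`` with self-consistently relaxed Drude
    displacements and the corresponding energy."""
    system = _System(model)
    if not system.polarizable:
        e = dimer_energy(model, state)
        return DimerState(state.quaternion, state.translation, np.zeros((2, 3)), e)
    R = _quat_matrix(_quat_normalize(state.quaternion))
    pos1 = system.pos
    pos2 = system.pos @ R.T + state.translation
    d0 = state.drude_disp if state.drude_disp is not None else np.zeros((2, 3))
    d1, d2, ok = _relax_drude(system, pos1, pos2, d0[0].copy(), d0[1].copy(), tol=tol)
    if not ok:
        raise ValueError("Drude relaxation did not converge (polarization catastrophe?)")
    new = DimerState(state.quaternion, state.translation, np.vstack([d1, d2]))
    new.energy = dimer_energy(model, new)
    return new


# ---------------------------------------------------------------------------
# objective with analytic gradient


class _Objective:
    """E(x) and dE/dx over the pose parameters.

    x = (quat[4], t[3]) unconstrained, or (quat[4], u[3]) with t = r_fixed
    u/|u| when the O-O distance is constrained.  The quaternion is normalized
    inside; its gauge (norm) direction has zero gradient by construction.
    For polarizable systems the Drude displacements are relaxed (warm-started
    from the previous evaluation) before the energy and the envelope gradient
    are computed.  A failed relaxation marks the pose collapsed and returns a
    large constant penalty so line searches back away.
    """

    PENALTY = 1.0e6

    def __init__(self, system: _System, r_fixed: Optional[float] = None,
                 max_drude_disp: float = 0.6):
        self.system = system
        self.r_fixed = r_fixed
        self.max_drude_disp = max_drude_disp
        self._warm = np.zeros((2, 3))
        self.collapsed = False

    def reset(self):
        self._warm = np.zeros((2, 3))
        self.collapsed = False

    def unpack(self, x):
        p = _quat_normalize(x[:4])
        if self.r_fixed is None:
            t = x[4:7]
        else:
            u = x[4:7]
            t = self.r_fixed * u / np.linalg.norm(u)
        return p, t

    def __call__(self, x):
        sysm = self.system
        p = _quat_normalize(x[:4])
        R = _quat_matrix(p)
        if self.r_fixed is None:
            t = x[4:7]
        else:
            u = x[4:7]
            nu = np.linalg.norm(u)
            t = self.r_fixed * u / nu
        pos1 = sysm.pos
        pos2 = sysm.pos @ R.T + t
        chg = sysm.chg

        if sysm.polarizable:
            d1, d2, ok = _relax_drude(sysm, pos1, pos2, self._warm[0].copy(),
                                      self._warm[1].copy())
            if not ok:
                self.collapsed = True
                self._warm = np.zeros((2, 3))
                return self.PENALTY, np.zeros(7)
            self._warm = np.vstack([d1, d2])
            a1 = np.vstack([pos1, pos1[sysm.iO] + d1])
            a2 = np.vstack([pos2, pos2[sysm.iO] + d2])
            c1 = np.append(chg, sysm.drude_q)
            c2 = np.append(chg, sysm.drude_q)
            e, g2 = _pair_energy_grad2(a1, c1, sysm.iO, a2, c2, sysm.iO,
                                       sysm.sigma, sysm.eps_kcal)
            e += sysm.drude_k * float(d1 @ d1 + d2 @ d2)
            locals2 = np.vstack([sysm.pos, sysm.pos[sysm.iO]])
        else:
            e, g2 = _pair_energy_grad2(pos1, chg, sysm.iO, pos2, chg, sysm.iO,
                                       sysm.sigma, sysm.eps_kcal)
            locals2 = sysm.pos

        gt = np.sum(g2, axis=0)
        gq_unit = _quat_chain(g2, locals2, p)
        nq = np.linalg.norm(x[:4])
        gq = (gq_unit - p * float(p @ gq_unit)) / nq  # chain through normalization
        if self.r_fixed is None:
            return e, np.concatenate([gq, gt])
        u = x[4:7]
        nu = np.linalg.norm(u)
        uhat = u / nu
        gu = (self.r_fixed / nu) * (gt - uhat * float(uhat @ gt))
        return e, np.concatenate([gq, gu])


# ---------------------------------------------------------------------------
# multi-start minimization


def _donor_distances(system: _System, p, t, disp):
    """Closest H...O(other molecule) distance for each molecule."""
    R = _quat_matrix(p)
    pos1 = system.pos
    pos2 = system.pos @ R.T + t
    o1, o2 = pos1[system.iO], pos2[system.iO]
    d1h = min(float(np.linalg.norm(pos1[i] - o2)) for i in system.h_idx)
    d2h = min(float(np.linalg.norm(pos2[i] - o1)) for i in system.h_idx)
    return d1h, d2h


def _classify_state(system: _System, p, t):
    """(single_donor, ref_topology) of a configuration.

    ``single_donor``: the two closest H...O(other) distances differ by more
    than 0.2 Å (excludes the cyclic doubly hydrogen-bonded state, where they
    are equal by symmetry).  ``ref_topology``: additionally, the donor
    molecule's plane contains the O-O line and the acceptor's does not — the
    arrangement of the reference dimer structure (and of the Cs-symmetric
    stationary state the parameterization protocol evaluates); this excludes
    planar two-molecule arrangements that can also carry a single donor.
    """
    R = _quat_matrix(p)
    pos2 = system.pos @ R.T + t
    o1, o2 = system.pos[system.iO], pos2[system.iO]
    n = (o2 - o1) / np.linalg.norm(o2 - o1)
    d1h, d2h = _donor_distances(system, p, t, None)
    single_donor = abs(d1h - d2h) > 0.2
    normal1 = np.array([1.0, 0.0, 0.0])  # canonical molecular plane is yz
    normal2 = R @ normal1
    if d1h <= d2h:
        donor_n, acceptor_n = normal1, normal2
    else:
        donor_n, acceptor_n = normal2, normal1
    ref_topology = (single_donor
                    and abs(float(donor_n @ n)) < 0.3
                    and abs(float(acceptor_n @ n)) > 0.3)
    return single_donor, ref_topology


def minimize_dimer(
    model: Model,
    *,
    n_restarts: int = 32,
    seed: int = 0,
    tol: float = 1e-6,
    r_oo_fixed: Optional[float] = None,
    basin: str = "hbond",
    r_range: tuple[float, float] = (2.5, 4.0),
    max_drude_disp: float = 0.6,
) -> DimerState:
    """Multi-start quasi-Newton minimization of the dimer energy.

    Restart poses draw the rotation uniformly over SO(3) and the O-O distance
    uniformly over ``r_range`` (seeded).  Each restart is minimized with
    L-BFGS-B using analytic gradients over the 6 rigid-body DOFs (Drude
    displacements relaxed adiabatically at every evaluation); the
    lowest-energy valid restart is returned.  ``tol`` is the acceptance bound
    on the projected-gradient max-norm at the returned state.

    ``basin`` selects which stationary state is reported.  These C2v
    point-charge layouts place charges far from the nuclei, and for several
    of them the cyclic, doubly hydrogen-bonded dimer (C2h-like, total dipole
    zero by symmetry) lies below the single-donor hydrogen-bonded structure
    that the reference dimer targets describe.  ``"hbond"`` (default, and the
    convention of the parameterization protocol: the dimer-dipole criterion
    is meaningless at the dipole-cancelling cyclic state) returns the lowest
    restart whose configuration has the reference dimer topology: a single
    donor (the two closest H...O(other) distances differ by at least 0.2 Å)
    with the donor molecule coplanar with the O-O line and the acceptor
    non-coplanar; ``"global"`` returns the lowest valid restart regardless of
    basin.

    Half the restarts start from hydrogen-bonded templates lying exactly on
    the Cs symmetry plane (randomized donor/acceptor tilts and O-O distance),
    the other half from fully random poses.  For the 3-point-geometry models
    the hydrogen-bonded state is a minimum only within the Cs-symmetric
    subspace (a saddle of the full 6-DOF surface, unstable toward the cyclic
    state); symmetric starts converge to it because the symmetry-breaking
    gradient component vanishes on the plane.  It is nevertheless the
    stationary state the dimer-matching protocol evaluates.

    A restart is invalid (collapsed) when its relaxation diverges, its relaxed
    Drude displacement exceeds ``max_drude_disp`` Å — outside the linear-
    response regime the point-Drude energy is unbounded below — or its final
    O-O distance is under 1.5 Å.  Per-restart diagnostics are returned in
    ``state.diagnostics``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    if basin not in ("hbond", "global"):
        raise ValueError(f"basin must be 'hbond' or 'global', got {basin!r}")
    system = _System(model)
    rng = np.random.default_rng(seed)
    obj = _Objective(system, r_fixed=r_oo_fixed, max_drude_disp=max_drude_disp)

    def _random_quat():
        q = rng.normal(size=4)
        return q / np.linalg.norm(q)

    def _seeded_pose():
        # hydrogen-bonded template on the Cs symmetry plane: molecule 1
        # donates along an O-O direction at angle theta from its C2 axis (one
        # O-H points near the acceptor oxygen); the acceptor C2 axis
        # continues outward at angle phi in the dimer plane, its molecular
        # plane perpendicular to it.  Starting on the symmetry plane is what
        # locates the hydrogen-bonded stationary state even for models where
        # it is a minimum only within the Cs subspace (see minimize_dimer).
        th = math.radians(rng.uniform(25.0, 85.0))
        ph = math.radians(rng.uniform(15.0, 85.0))
        n = np.array([0.0, math.sin(th), math.cos(th)])
        a = np.array([0.0, math.sin(th + ph), math.cos(th + ph)])
        b = np.array([1.0, 0.0, 0.0])
        R = np.column_stack([np.cross(b, a), b, a])
        return _matrix_to_quat(R), n

    records = []
    best = None
    best_global = math.inf
    seed_r = (max(r_range[0], 2.6), min(r_range[1], 3.4))
    for i in range(n_restarts):
        if i % 2 == 1:
            quat, direction = _seeded_pose()
            r0 = rng.uniform(*seed_r)
        else:
            quat = _random_quat()
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            r0 = rng.uniform(*r_range)
        if r_oo_fixed is None:
            x0 = np.concatenate([quat, r0 * direction])
        else:
            x0 = np.concatenate([quat, direction])
        obj.reset()
        res = minimize(obj, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": 4000, "ftol": 1e-14, "gtol": 1e-10,
                                "maxcor": 20})
        p, t = obj.unpack(res.x)
        roo = np.linalg.norm(t)
        disp = obj._warm.copy() if system.polarizable else None
        dmax = float(np.max(np.linalg.norm(disp, axis=1))) if disp is not None else 0.0
        gnorm = float(np.max(np.abs(res.jac)))
        collapsed = (obj.collapsed or roo < 1.5 or dmax > max_drude_disp
                     or res.fun >= _Objective.PENALTY)
        if not collapsed:
            single_donor, ref_topology = _classify_state(system, p, t)
        else:
            single_donor = ref_topology = False
        records.append({
            "restart": i, "energy": float(res.fun), "r_oo": float(roo),
            "grad_norm": gnorm, "collapsed": bool(collapsed),
            "converged": bool(res.success or gnorm < tol),
            "single_donor": bool(single_donor),
            "ref_topology": bool(ref_topology),
            "max_drude_disp": dmax, "nit": int(res.nit),
        })
        if collapsed:
            continue
        best_global = min(best_global, float(res.fun))
        if basin == "hbond" and not ref_topology:
            continue
        if best is None or res.fun < best[0]:
            best = (float(res.fun), p, t, disp, gnorm)

    if best is None:
        raise RuntimeError(
            f"no restart converged to a valid minimum in the {basin!r} basin; "
            f"diagnostics: {records}"
        )
    energy, p, t, disp, gnorm = best
    state = DimerState(p, t, disp, energy,
                       diagnostics={"restarts": records, "seed": seed,
                                    "grad_norm": gnorm, "tol": tol,
                                    "r_oo_fixed": r_oo_fixed, "basin": basin,
                                    "below_basin_energy": (
                                        None if best_global >= energy - 1e-9
                                        else best_global)})
    if gnorm > tol:
        state.diagnostics["warning"] = (
            f"projected gradient max-norm {gnorm:.2e} above tol {tol:.2e}"
        )
    return state


# ---------------------------------------------------------------------------
# geometry descriptors


def _angle_deg(a, b):
    c = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def dimer_geometry(model: Model, state: DimerState, *,
                   theta0: float = 57.9, phi0: float = 55.6) -> DimerGeometry:
    """Extract r(OO), the donor/acceptor C2-axis angles and the total dipole.

    The donor is the molecule owning the hydrogen closest to the other
    oxygen; both angles are measured against the donor-to-acceptor O-O
    direction.  The total dipole is |sum q_i r_i| over all sites (Drude
    included), converted to Debye; the dimer is neutral, so it is
    origin-independent.
    """
    system = _System(model)
    pos1, chg1, pos2, chg2 = _assemble(system, state)
    R = _quat_matrix(_quat_normalize(state.quaternion))
    o1 = pos1[system.iO]
    o2 = pos2[system.iO]
    r_oo = float(np.linalg.norm(o2 - o1))

    axis1 = _EZ
    axis2 = R @ _EZ
    h1 = min(float(np.linalg.norm(pos1[i] - o2)) for i in system.h_idx)
    h2 = min(float(np.linalg.norm(pos2[i] - o1)) for i in system.h_idx)
    if h1 <= h2:  # molecule 1 donates
        n = (o2 - o1) / r_oo
        theta = _angle_deg(axis1, n)
        phi = _angle_deg(axis2, n)
    else:
        n = (o1 - o2) / r_oo
        theta = _angle_deg(axis2, n)
        phi = _angle_deg(axis1, n)

    dip_vec = chg1 @ pos1 + chg2 @ pos2
    total_dipole = float(np.linalg.norm(dip_vec)) * DEBYE_PER_EA
    angle_error = abs(theta - theta0) + abs(phi - phi0)
    return DimerGeometry(r_oo=r_oo, theta=theta, phi=phi,
                         total_dipole=total_dipole, angle_error=angle_error)
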