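"""Multipole moments of point-charge distributions with C2v symmetry.

A water molecule is placed in its canonical frame: the C2 symmetry axis along
z, the H–O–H plane equal to the yz plane, oxygen at the origin.  In that frame
the traceless quadrupole tensor is diagonal,

    Q = diag(-Qt - Q0/2, Qt - Q0/2, Q0),

and the z-slice of the traceless octupole tensor is

    O[:, :, z] = diag(-Ωt - Ω0/2, Ωt - Ω0/2, Ω0),

so the full electrostatic signature of the molecule up to octupole order is
the five scalars (μ, Qt, Q0, Ωt, Ω0).  Moments are reported in Debye-based
units (D, D·Å, D·Å²); computations run in e·Å^n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import DEBYE_PER_EA

SITE_KINDS = ("hydrogen", "oxygen", "extra_point", "drude")


@dataclass(frozen=True)
class ChargeSite:
    """A point charge at a Cartesian position (Å, e)."""

    position: tuple[float, float, float]
    charge: float
    kind: str = "extra_point"

    def __post_init__(self):
        if self.kind not in SITE_KINDS:
            raise ValueError(f"unknown site kind {self.kind!r}; expected one of {SITE_KINDS}")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("site position must be finite")
        if not math.isfinite(self.charge):
            raise ValueError("site charge must be finite")


@dataclass(frozen=True)
class MultipoleSet:
    """Monomer multipole targets: μ [D], Qt, Q0 [D·Å], Ωt, Ω0 [D·Å²].

    The octupoles are optional in the sense that a reference lacking them
    (e.g. an experimental set) stores ``nan``; constructions that need them
    raise on nan input.
    """

    mu: float
    Qt: float
    Q0: float
    Omega_t: float = float("nan")
    Omega_0: float = float("nan")
    name: str = ""

    def __post_init__(self):
        if not math.isfinite(self.mu) or self.mu < 0:
            raise ValueError(f"dipole magnitude must be finite and >= 0, got {self.mu}")
        for label in ("Qt", "Q0"):
            if not math.isfinite(getattr(self, label)):
                raise ValueError(f"{label} must be finite")

    @property
    def has_octupoles(self) -> bool:
        return math.isfinite(self.Omega_t) and math.isfinite(self.Omega_0)

    def to_atomic(self) -> "MultipoleSet":
        """Return the same moments in e·Å^n units (divide by 4.80320)."""
        d = DEBYE_PER_EA
        return MultipoleSet(
            self.mu / d, self.Qt / d, self.Q0 / d,
            self.Omega_t / d, self.Omega_0 / d, name=self.name,
        )

    def to_debye(self) -> "MultipoleSet":
        """Inverse of :meth:`to_atomic`."""
        d = DEBYE_PER_EA
        return MultipoleSet(
            self.mu * d, self.Qt * d, self.Q0 * d,
            self.Omega_t * d, self.Omega_0 * d, name=self.name,
        )


def _moment_components(pos: np.ndarray, chg: np.ndarray):
    """Raw dipole vector, traceless quadrupole tensor and octupole z-slice
    components (e·Å^n) of a point-charge set."""
    r2 = np.sum(pos * pos, axis=1)
    dip = chg @ pos

    # Q_ij = 1/2 sum q (3 r_i r_j - r^2 delta_ij)
    quad = 0.5 * (3.0 * (pos.T * chg) @ pos - np.diag([np.sum(chg * r2)] * 3).astype(float))

    # O_ijk = 1/6 sum q [15 r_i r_j r_k - 3 r^2 (r_i d_jk + r_j d_ik + r_k d_ij)]
    # Only the k = z slice is needed here.
    z = pos[:, 2]
    qr2 = chg * r2
    ez = np.array([0.0, 0.0, 1.0])
    v = 0.5 * (pos.T @ qr2)  # 1/2 sum q r^2 r_i
    o_slice = (15.0 / 6.0) * (pos.T * (chg * z)) @ pos
    o_slice -= np.outer(v, ez) + np.outer(ez, v)
    o_slice -= 0.5 * np.sum(qr2 * z) * np.eye(3)
    return dip, quad, o_slice


def moments_from_charges(sites, *, tol: float = 1e-7) -> MultipoleSet:
    """Compute (μ, Qt, Q0, Ωt, Ω0) of a neutral C2v point-charge set.

    The set must be oriented in the canonical frame (C2 axis = z, molecular
    plane = yz).  The dipole is μ = |Σ q z|; the quadrupole scalars are read
    off the diagonal of the traceless tensor and the octupole scalars off the
    z-slice, with Ω0 = O_zzz and Ωt = O_yyz + Ω0/2.

    Raises if the set is not neutral (the moments would be origin-dependent)
    or if off-axis components exceed ``tol`` (C2v assumption violated).
    """
    sites = list(sites)
    pos = np.array([s.position for s in sites], dtype=float)
    chg = np.array([s.charge for s in sites], dtype=float)
    net = float(np.sum(chg))
    if abs(net) > 1e-9:
        raise ValueError(f"point-charge set is not neutral: net charge {net:.3e} e")

    dip, quad, o_slice = _moment_components(pos, chg)

    scale = max(1.0, float(np.max(np.abs(chg))) * max(1.0, float(np.max(np.abs(pos)))))
    off_axis = max(
        abs(dip[0]), abs(dip[1]),
        abs(quad[0, 1]), abs(quad[0, 2]), abs(quad[1, 2]),
        abs(o_slice[0, 1]), abs(o_slice[0, 2]), abs(o_slice[1, 2]),
    )
    if off_axis > tol * scale:
        raise ValueError(
            "charge distribution violates the C2v canonical-frame assumption "
            f"(largest off-axis moment component {off_axis:.3e} e·Å^n)"
        )

    mu = abs(dip[2])
    q0 = quad[2, 2]
    qt = 0.5 * (quad[1, 1] - quad[0, 0])
    omega0 = o_slice[2, 2]
    omegat = o_slice[1, 1] + omega0 / 2.0

    d = DEBYE_PER_EA
    return MultipoleSet(mu * d, qt * d, q0 * d, omegat * d, omega0 * d)
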