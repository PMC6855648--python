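"""Drude-oscillator polarizability on a 3-point rigid base.

A massless charged particle (charge Q_D) is tethered to the oxygen by an
isotropic virtual bond with equilibrium length 0 and force constant k, in the
AMBER bond-energy convention

    U(d) = k d²          (restoring force 2 k d),

the convention in which the tabulated k = 1000 kcal/mol/Å² reproduces the
published dimer results.  To keep the unpolarized charge distribution
identical to the rigid base, the oxygen charge is shifted to -2q - Q_D so
that oxygen + Drude together carry -2q.

The nominal polarizability label α of such an oscillator follows the AMBER
charge convention

    Q_D = sqrt(α k) / 18.2223  e,

used for both directions of the α ↔ Q_D conversion (it reproduces the
tabulated (α, Q_D) pairs to all printed digits).  The true linear response of
the oscillator — induced dipole per unit field — is

    α_mech = C Q_D² / (2 k)  with  C = 332.0637 kcal·Å/(mol·e²),

i.e. very nearly α/2; :attr:`DrudeSpec.mechanical_alpha` exposes it.

The Drude particle has no Coulomb interaction with any site of its own
molecule (only the spring couples it to its oxygen; in a rigid molecule any
constant intramolecular term is irrelevant).  All intermolecular pairs
interact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .constants import AMBER_SQRT_COULOMB, COULOMB_KCAL
from .builder import ModelGeometry
from .multipoles import ChargeSite


def drude_charge_from_alpha(alpha: float, k: float = 1000.0) -> float:
    """Drude charge (e) implied by polarizability ``alpha`` (Å³) and spring
    constant ``k`` (kcal/mol/Å²): Q_D = sqrt(α k)/18.2223."""
    if alpha < 0:
        raise ValueError(f"polarizability must be >= 0, got {alpha}")
    if k <= 0:
        raise ValueError(f"spring constant must be positive, got {k}")
    return math.sqrt(alpha * k) / AMBER_SQRT_COULOMB


def alpha_from_drude_charge(q_drude: float, k: float = 1000.0) -> float:
    """Exact inverse of :func:`drude_charge_from_alpha`."""
    if k <= 0:
        raise ValueError(f"spring constant must be positive, got {k}")
    return (q_drude * AMBER_SQRT_COULOMB) ** 2 / k


@dataclass(frozen=True)
class DrudeSpec:
    """Polarizability α (Å³), spring constant k (kcal/mol/Å²) and the derived
    Drude charge Q_D (e)."""

    alpha: float
    k: float = 1000.0
    q_drude: float = field(default=float("nan"))

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError(f"polarizability must be >= 0, got {self.alpha}")
        if self.k <= 0:
            raise ValueError(f"spring constant must be positive, got {self.k}")
        if math.isnan(self.q_drude):
            object.__setattr__(self, "q_drude", drude_charge_from_alpha(self.alpha, self.k))
        else:
            expect = drude_charge_from_alpha(self.alpha, self.k)
            if abs(self.q_drude - expect) > 1e-9 * max(1.0, expect):
                raise ValueError(
                    f"inconsistent DrudeSpec: alpha={self.alpha} Å³ at k={self.k} implies "
                    f"Q_D={expect:.6f} e, got {self.q_drude}"
                )

    @classmethod
    def from_charge(cls, q_drude: float, k: float = 1000.0) -> "DrudeSpec":
        return cls(alpha=alpha_from_drude_charge(q_drude, k), k=k, q_drude=q_drude)

    @property
    def mechanical_alpha(self) -> float:
        """True linear response C Q_D²/(2k) in Å³ of the U = k d² oscillator
        (≈ alpha/2; the nominal ``alpha`` is the tabulated label)."""
        return COULOMB_KCAL * self.q_drude**2 / (2.0 * self.k)


@dataclass(frozen=True)
class PolarizableModel:
    """A 3-point rigid base plus a Drude oscillator on the oxygen."""

    base: ModelGeometry
    spec: DrudeSpec

    def __post_init__(self):
        if self.base.n_points != 3:
            raise ValueError(
                "Drude attachment is defined for 3-point bases only, "
                f"got a {self.base.n_points}-point model"
            )

    @property
    def oxygen_charge(self) -> float:
        """-2q - Q_D: oxygen + Drude together carry the base's -2q."""
        return -2.0 * self.base.q - self.spec.q_drude

    @property
    def lj_sigma(self) -> float:
        return self.base.lj_sigma

    @property
    def lj_epsilon(self) -> float:
        return self.base.lj_epsilon

    def with_lj(self, sigma: float, epsilon_kj: float) -> "PolarizableModel":
        return PolarizableModel(self.base.with_lj(sigma, epsilon_kj), self.spec)

    def to_sites(self, drude_displacement=(0.0, 0.0, 0.0)) -> list[ChargeSite]:
        """Canonical-frame sites; the Drude sits at oxygen + displacement."""
        q, y1, z2 = self.base.q, self.base.y1, self.base.z2
        dx, dy, dz = drude_displacement
        return [
            ChargeSite((0.0, y1, z2), q, "hydrogen"),
            ChargeSite((0.0, -y1, z2), q, "hydrogen"),
            ChargeSite((0.0, 0.0, 0.0), self.oxygen_charge, "oxygen"),
            ChargeSite((dx, dy, dz), self.spec.q_drude, "drude"),
        ]


def attach_drude(base: ModelGeometry, spec: DrudeSpec) -> PolarizableModel:
    """Attach a Drude oscillator to the oxygen of a 3-point rigid base."""
    return PolarizableModel(base=base, spec=spec)
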