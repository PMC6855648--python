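"""Physical constants and unit conversions.

The internal unit system is {e, Å, kcal/mol}: every construction equation is
dimensionally consistent only in a single charge-length system, so Debye-based
quantities are converted at the boundary and converted back for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Constants:
    """Electrostatic constants in the {e, Å, kcal/mol} unit system."""

    #: Debye per e·Å (1 e·Å = 4.80320 D).
    debye_per_eA: float = 4.80320
    #: Coulomb energy constant, kcal·Å/(mol·e²).
    coulomb_kcal: float = 332.0637
    #: sqrt of the Coulomb constant as used by AMBER, (kcal·Å/mol)^1/2 / e.
    amber_sqrt_coulomb: float = 18.2223
    #: kJ per kcal (thermochemical calorie).
    kj_per_kcal: float = 4.184


CONSTANTS = Constants()

DEBYE_PER_EA = CONSTANTS.debye_per_eA
COULOMB_KCAL = CONSTANTS.coulomb_kcal
AMBER_SQRT_COULOMB = CONSTANTS.amber_sqrt_coulomb
KJ_PER_KCAL = CONSTANTS.kj_per_kcal

# Unit tag -> (dimension family, factor to the family's internal base unit).
# Moment families use e·Å^n as base; energy uses kcal/mol.
_UNIT_TABLE = {
    "D": ("dipole", 1.0 / DEBYE_PER_EA),
    "e*A": ("dipole", 1.0),
    "D*A": ("quadrupole", 1.0 / DEBYE_PER_EA),
    "e*A^2": ("quadrupole", 1.0),
    "D*A^2": ("octupole", 1.0 / DEBYE_PER_EA),
    "e*A^3": ("octupole", 1.0),
    "kcal/mol": ("energy", 1.0),
    "kJ/mol": ("energy", 1.0 / KJ_PER_KCAL),
}

# Accept the pretty spellings as aliases.
_ALIASES = {
    "e·Å": "e*A",
    "D·Å": "D*A",
    "e·Å²": "e*A^2",
    "D·Å²": "D*A^2",
    "e·Å³": "e*A^3",
}


def _resolve(tag: str) -> tuple[str, float]:
    key = _ALIASES.get(tag, tag)
    if key not in _UNIT_TABLE:
        known = sorted(set(_UNIT_TABLE) | set(_ALIASES))
        raise ValueError(f"unknown unit tag {tag!r}; known tags: {known}")
    return _UNIT_TABLE[key]


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact linear conversion between unit tags of the same dimension.

    Supported tags: ``D``/``e*A`` (dipole), ``D*A``/``e*A^2`` (quadrupole),
    ``D*A^2``/``e*A^3`` (octupole), ``kcal/mol``/``kJ/mol`` (energy), plus
    the unicode spellings (``e·Å`` etc.).
    """
    fam_from, fac_from = _resolve(from_unit)
    fam_to, fac_to = _resolve(to_unit)
    if fam_from != fam_to:
        raise ValueError(
            f"incompatible units: {from_unit!r} is a {fam_from}, {to_unit!r} is a {fam_to}"
        )
    return value * fac_from / fac_to
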