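"""Plain-text (TOML) run configuration.

Sections:

``[reference]`` — either ``name = "gas_exp"`` (a packaged set) or explicit
``mu, Qt, Q0, Omega_t, Omega_0`` in Debye-based units.

``[targets]`` — ``p_dimer`` (D), ``r_oo`` (Å), ``theta0``, ``phi0`` (deg),
``dipole_tol`` (relative); all optional, defaulting to the reference dimer.

``[optimizer]`` — ``mu_bracket``, ``alpha_range`` (two-element lists),
``n_restarts``, ``seed``.

``[lj]`` — ``epsilon`` (kJ/mol, required by the fitting commands) and
optionally a fixed ``sigma`` (Å).
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field

from .multipoles import MultipoleSet
from .optimize import ReferenceTargets


@dataclass
class RunConfig:
    reference: MultipoleSet | None
    targets: ReferenceTargets
    optimizer: dict = field(default_factory=dict)
    lj: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    ref = None
    ref_sec = raw.get("reference", {})
    if "name" in ref_sec:
        from .reference import load_reference

        ref = load_reference(ref_sec["name"])
    elif ref_sec:
        ref = MultipoleSet(
            mu=float(ref_sec["mu"]),
            Qt=float(ref_sec["Qt"]),
            Q0=float(ref_sec["Q0"]),
            Omega_t=float(ref_sec.get("Omega_t", float("nan"))),
            Omega_0=float(ref_sec.get("Omega_0", float("nan"))),
            name=str(ref_sec.get("label", "config")),
        )

    t = raw.get("targets", {})
    targets = ReferenceTargets(
        p_dimer=float(t.get("p_dimer", 2.68)),
        r_oo_ref=float(t.get("r_oo", 2.91)),
        theta0=float(t.get("theta0", 57.9)),
        phi0=float(t.get("phi0", 55.6)),
        dipole_tol=float(t.get("dipole_tol", 0.001)),
    )
    return RunConfig(
        reference=ref,
        targets=targets,
        optimizer=dict(raw.get("optimizer", {})),
        lj=dict(raw.get("lj", {})),
    )
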