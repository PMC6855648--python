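"""Packaged reference data and the synthetic-reference generator.

Three reference multipole sets ship with the package ("gas_exp", "gas_qm",
"liquid_mp2_4mm"), together with the tabulated parameters of the rigid models
built from them (plus TIP3P/OPC3/OPC comparison rows) and of the two 3-point
polarizable models.  The gas-phase experimental set has no measured
octupoles; following the construction protocol, the gas-QM octupoles are
substituted when that set is loaded (the ``octupole_source`` column records
the borrowing).

Everything is stored as plain CSV under ``watermodels/data`` with a
``provenance`` column naming the source row; values are verbatim, never
recomputed.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builder import ModelGeometry
from .drude import DrudeSpec, PolarizableModel, attach_drude
from .multipoles import MultipoleSet
from . import builder


def _read_data_csv(name: str) -> pd.DataFrame:
    with resources.files("watermodels.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, na_values=["—"], keep_default_na=True,
                           float_precision="round_trip")


@dataclass
class ReferenceLibrary:
    """Lazy container over the packaged reference tables."""

    multipole_sets: dict = field(default_factory=dict)
    rigid_models: pd.DataFrame | None = None
    polarizable_models: pd.DataFrame | None = None

    def _load(self):
        if self.multipole_sets:
            return
        msets = _read_data_csv("multipole_sets.csv").set_index("name")
        raw = {}
        for name, row in msets.iterrows():
            raw[name] = row
        for name, row in msets.iterrows():
            omega_t, omega_0 = row["Omega_t"], row["Omega_0"]
            src = row.get("octupole_source")
            if isinstance(src, str) and src:
                omega_t = raw[src]["Omega_t"]
                omega_0 = raw[src]["Omega_0"]
            self.multipole_sets[name] = MultipoleSet(
                mu=float(row["mu"]), Qt=float(row["Qt"]), Q0=float(row["Q0"]),
                Omega_t=float(omega_t) if pd.notna(omega_t) else float("nan"),
                Omega_0=float(omega_0) if pd.notna(omega_0) else float("nan"),
                name=name,
            )
        self.rigid_models = _read_data_csv("rigid_models.csv").set_index("name")
        self.polarizable_models = _read_data_csv("polarizable_models.csv").set_index("name")

    # -- lookups -----------------------------------------------------------

    def available(self) -> list[str]:
        self._load()
        keys = list(self.multipole_sets)
        keys += [f"table2/{n}" for n in self.rigid_models.index]
        keys += [f"table3/{n}" for n in self.polarizable_models.index]
        return keys

    def load(self, name: str):
        """Return the packaged object for ``name``.

        Multipole-set names ("gas_exp", ...) give a :class:`MultipoleSet`;
        "table2/<set>/<n>" (e.g. "table2/gas_exp/4") and "table2/tip3p" give
        a :class:`ModelGeometry` with its tabulated LJ parameters;
        "table3/alpha" and "table3/alpha_and_mu" give a
        :class:`PolarizableModel`.
        """
        self._load()
        if name in self.multipole_sets:
            return self.multipole_sets[name]
        if name.startswith("table2/"):
            key = name[len("table2/"):]
            if key in self.rigid_models.index:
                return self._rigid_from_row(key)
        if name.startswith("table3/"):
            key = name[len("table3/"):]
            if key in self.polarizable_models.index:
                return self._polarizable_from_row(key)
        raise KeyError(
            f"unknown reference {name!r}; available: {self.available()}"
        )

    def _rigid_from_row(self, key: str) -> ModelGeometry:
        row = self.rigid_models.loc[key]
        n = int(row["n"])
        return ModelGeometry(
            n_points=n,
            q=float(row["q"]),
            y1=float(row["y1"]),
            z2=float(row["z2"]),
            z1=float(row["z1"]) if pd.notna(row["z1"]) else 0.0,
            x1=float(row["x1"]) if pd.notna(row["x1"]) else 0.0,
            lj_sigma=float(row["sigma"]),
            lj_epsilon=float(row["epsilon"]),
            name=key,
        )

    def _polarizable_from_row(self, key: str) -> PolarizableModel:
        row = self.polarizable_models.loc[key]
        base = ModelGeometry(
            n_points=3,
            q=float(row["q"]),
            y1=float(row["y1"]),
            z2=float(row["z2"]),
            lj_sigma=float(row["sigma"]),
            lj_epsilon=float(row["epsilon"]),
            name=key,
        )
        spec = DrudeSpec.from_charge(float(row["Q_D"]), k=float(row["k"]))
        return attach_drude(base, spec)


LIBRARY = ReferenceLibrary()


def load_reference(name: str):
    """Load a packaged reference object by name (see
    :meth:`ReferenceLibrary.load`)."""
    return LIBRARY.load(name)


_DEFAULT_RANGES = {
    "mu": (1.6, 2.8),
    "Qt": (2.2, 3.2),
    "Q0": (0.02, 0.30),
    "Omega_t": (1.6, 2.3),
    "Omega_0": (-2.0, -1.0),
}


def generate_synthetic_reference(seed: int, ranges: dict | None = None,
                                 max_tries: int = 1000) -> MultipoleSet:
    """Draw a random but buildable multipole set for property tests.

    Each field is uniform over its range (defaults bracket the packaged
    reference sets); a draw is accepted only if both the 3-point and the
    4-point constructions succeed with real, positive-charge solutions at a
    monomer dipole equal to the drawn μ.  Same seed, same set.
    """
    rng = np.random.default_rng(seed)
    r = dict(_DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    for _ in range(max_tries):
        vals = {k: float(rng.uniform(*r[k])) for k in
                ("mu", "Qt", "Q0", "Omega_t", "Omega_0")}
        ref = MultipoleSet(**vals, name=f"synthetic-{seed}")
        try:
            builder.build_3point(ref, ref.mu)
            builder.build_4point(ref, ref.mu)
        except ValueError:
            continue
        return ref
    raise RuntimeError(f"no buildable multipole set found in {max_tries} draws")
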