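"""File formats: model parameter CSV, extended XYZ, PDB and JSON manifests.

Model tables use the column layout
``name, n, q, z1, z2, y1, x1, mu, sigma, epsilon[, Q_D, alpha, k]`` with an
em-dash ("—") for missing entries, matching the published parameter tables.

The extended-XYZ dialect is one atom per line,
``element x y z charge kind``, with a ``Properties=`` comment header; element
symbols are H / O / EP (extra point) / DR (Drude).  Writers emit full double
precision so read/write round-trips are exact to 1e-12.
"""

from __future__ import annotations

import json
import math
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .builder import ModelGeometry
from .drude import DrudeSpec, PolarizableModel
from .multipoles import ChargeSite

MISSING = "—"

_ELEMENT_OF_KIND = {"hydrogen": "H", "oxygen": "O", "extra_point": "EP", "drude": "DR"}
_KIND_OF_ELEMENT = {v: k for k, v in _ELEMENT_OF_KIND.items()}

Model = Union[ModelGeometry, PolarizableModel]


# ---------------------------------------------------------------------------
# model parameter tables


def _model_row(model: Model) -> dict:
    if isinstance(model, PolarizableModel):
        base = model.base
        row = _model_row(base)
        row.update({"name": base.name, "Q_D": model.spec.q_drude,
                    "alpha": model.spec.alpha, "k": model.spec.k})
        return row
    return {
        "name": model.name,
        "n": model.n_points,
        "q": model.q,
        "z1": model.z1 if model.n_points != 3 else math.nan,
        "z2": model.z2,
        "y1": model.y1,
        "x1": model.x1 if model.n_points == 5 else math.nan,
        "mu": model.mu,
        "sigma": model.lj_sigma,
        "epsilon": model.lj_epsilon,
        "Q_D": math.nan,
        "alpha": math.nan,
        "k": math.nan,
    }


def write_models_csv(models: Iterable[Model], path) -> None:
    """Write models as a parameter table (one row each, missing fields as —)."""
    df = pd.DataFrame([_model_row(m) for m in models])
    df.to_csv(path, index=False, na_rep=MISSING, float_format="%.17g")


def read_models_csv(path) -> list[Model]:
    """Read a parameter table back into model objects."""
    df = pd.read_csv(path, na_values=[MISSING], float_precision="round_trip")
    out: list[Model] = []
    for _, row in df.iterrows():
        geom = ModelGeometry(
            n_points=int(row["n"]),
            q=float(row["q"]),
            y1=float(row["y1"]),
            z2=float(row["z2"]),
            z1=float(row["z1"]) if pd.notna(row.get("z1")) else 0.0,
            x1=float(row["x1"]) if pd.notna(row.get("x1")) else 0.0,
            lj_sigma=float(row["sigma"]) if pd.notna(row.get("sigma")) else math.nan,
            lj_epsilon=float(row["epsilon"]) if pd.notna(row.get("epsilon")) else math.nan,
            name=str(row["name"]) if pd.notna(row.get("name")) else "",
        )
        if "Q_D" in df.columns and pd.notna(row["Q_D"]):
            spec = DrudeSpec.from_charge(float(row["Q_D"]), k=float(row["k"]))
            out.append(PolarizableModel(geom, spec))
        else:
            out.append(geom)
    return out


# ---------------------------------------------------------------------------
# extended XYZ


def write_xyz(path, sites: Iterable[ChargeSite], comment: str = "") -> None:
    sites = list(sites)
    lines = [str(len(sites)),
             f"Properties=species:S:1:pos:R:3:charge:R:1:kind:S:1 {comment}".rstrip()]
    for s in sites:
        el = _ELEMENT_OF_KIND[s.kind]
        x, y, z = s.position
        lines.append(f"{el} {x:.14e} {y:.14e} {z:.14e} {s.charge:.14e} {s.kind}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path) -> list[ChargeSite]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].split()[0])
    sites = []
    for line in lines[2:2 + n]:
        parts = line.split()
        el, x, y, z, q = parts[:5]
        kind = parts[5] if len(parts) > 5 else _KIND_OF_ELEMENT.get(el, "extra_point")
        sites.append(ChargeSite((float(x), float(y), float(z)), float(q), kind))
    return sites


def dimer_sites(model: Model, state) -> list[ChargeSite]:
    """All sites of both molecules at a dimer state (Drude at its displaced
    position), suitable for XYZ/PDB export."""
    from .dimer import _System, _assemble

    system = _System(model)
    pos1, chg1, pos2, chg2 = _assemble(system, state)
    kinds = list(system.kinds) + (["drude"] if system.polarizable else [])
    sites = []
    for pos, chg in ((pos1, chg1), (pos2, chg2)):
        for p, q, k in zip(pos, chg, kinds):
            sites.append(ChargeSite(tuple(p), float(q), k))
    return sites


def write_dimer_xyz(model: Model, state, path, comment: str = "") -> None:
    energy = state.energy
    write_xyz(path, dimer_sites(model, state),
              comment=f"energy_kcal_mol={energy:.10f} {comment}".rstrip())


# ---------------------------------------------------------------------------
# PDB (pseudo-atoms for extra points and Drude particles)

_PDB_NAME = {"hydrogen": "H", "oxygen": "O", "extra_point": "EP", "drude": "DR"}


def write_pdb(path, sites: Iterable[ChargeSite], title: str = "water model dimer") -> None:
    lines = [f"TITLE     {title}"]
    counters: dict[str, int] = {}
    for i, s in enumerate(sites, start=1):
        base = _PDB_NAME[s.kind]
        counters[base] = counters.get(base, 0) + 1
        name = f"{base}{counters[base]}"[:4]
        x, y, z = s.position
        element = "H" if s.kind == "hydrogen" else ("O" if s.kind == "oxygen" else "X")
        lines.append(
            f"HETATM{i:>5} {name:<4} WAT A{1:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{s.charge:6.2f}          {element:>2}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# run manifests


def write_manifest(path, payload: dict) -> None:
    """JSON run manifest (inputs, seed, outputs, package versions)."""
    import scipy

    import watermodels

    meta = {
        "versions": {
            "watermodels": watermodels.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    meta.update(payload)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
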