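"""Packaged reference data, the synthetic-reference generator, and the file
formats (model CSV, extended XYZ, PDB, manifests, TOML config)."""

import json

import numpy as np
import pytest

from watermodels import (
    MultipoleSet,
    PolarizableModel,
    build_4point,
    generate_synthetic_reference,
    load_reference,
    minimize_dimer,
    moments_from_charges,
)
from watermodels import io
from watermodels.config import load_config
from watermodels.dimer import coulomb_lj_energy
from watermodels.reference import LIBRARY


class TestReferenceLibrary:
    def test_multipole_sets_match_published_values(self):
        ge = load_reference("gas_exp")
        assert (ge.mu, ge.Qt, ge.Q0) == (1.86, 2.57, 0.11)
        gq = load_reference("gas_qm")
        assert (gq.mu, gq.Qt, gq.Q0, gq.Omega_t, gq.Omega_0) == \
            (1.81, 2.49, 0.08, 1.93, -1.35)
        lq = load_reference("liquid_mp2_4mm")
        assert (lq.mu, lq.Qt, lq.Q0, lq.Omega_t, lq.Omega_0) == \
            (2.49, 2.93, 0.13, 2.09, -1.73)

    def test_gas_exp_borrows_gas_qm_octupoles(self):
        ge = load_reference("gas_exp")
        gq = load_reference("gas_qm")
        assert ge.Omega_t == gq.Omega_t and ge.Omega_0 == gq.Omega_0

    def test_rigid_model_rows(self):
        m = load_reference("table2/gas_exp/4")
        assert m.q == 1.9094 and m.lj_sigma == 3.2999 and m.lj_epsilon == 0.7196
        tip3p = load_reference("table2/tip3p")
        assert tip3p.n_points == 3 and tip3p.q == 0.4170

    def test_polarizable_rows(self):
        m = load_reference("table3/alpha_and_mu")
        assert isinstance(m, PolarizableModel)
        assert m.spec.q_drude == 2.6261
        assert m.spec.alpha == pytest.approx(2.2900, abs=2e-4)
        assert m.base.q == 0.1700 and m.lj_sigma == 3.3786

    def test_unknown_name_lists_available_keys(self):
        with pytest.raises(KeyError, match="gas_qm"):
            load_reference("nope")

    def test_available_contains_all_families(self):
        keys = LIBRARY.available()
        assert "gas_exp" in keys
        assert "table2/opc" in keys
        assert "table3/alpha" in keys


class TestSyntheticReference:
    def test_same_seed_same_set(self):
        a = generate_synthetic_reference(3)
        b = generate_synthetic_reference(3)
        assert a == b

    @pytest.mark.parametrize("seed", range(5))
    def test_generated_sets_are_buildable_and_round_trip(self, seed):
        ref = generate_synthetic_reference(seed)
        model = build_4point(ref, ref.mu)
        got = moments_from_charges(model.to_sites()).to_atomic()
        want = ref.to_atomic()
        assert got.mu == pytest.approx(want.mu, abs=1e-6)
        assert got.Qt == pytest.approx(want.Qt, abs=1e-6)
        assert got.Q0 == pytest.approx(want.Q0, abs=1e-6)
        assert got.Omega_t - got.Omega_0 / 2 == pytest.approx(
            want.Omega_t - want.Omega_0 / 2, abs=1e-6)

    def test_collapsed_ranges_return_that_point(self):
        gq = load_reference("gas_qm")
        ranges = {k: (getattr(gq, v), getattr(gq, v)) for k, v in
                  [("mu", "mu"), ("Qt", "Qt"), ("Q0", "Q0"),
                   ("Omega_t", "Omega_t"), ("Omega_0", "Omega_0")]}
        ref = generate_synthetic_reference(0, ranges)
        for f in ("mu", "Qt", "Q0", "Omega_t", "Omega_0"):
            assert getattr(ref, f) == getattr(gq, f)


class TestModelCsv:
    def test_round_trip_preserves_all_fields(self, tmp_path, rigid4_gas_exp,
                                             polarizable_global):
        path = tmp_path / "models.csv"
        io.write_models_csv([rigid4_gas_exp, polarizable_global], path)
        back = io.read_models_csv(path)
        assert len(back) == 2
        rigid, pol = back
        for f in ("n_points", "q", "y1", "z1", "z2", "x1", "lj_sigma", "lj_epsilon"):
            assert getattr(rigid, f) == getattr(rigid4_gas_exp, f)
        assert isinstance(pol, PolarizableModel)
        assert pol.spec.q_drude == polarizable_global.spec.q_drude
        assert pol.base.y1 == polarizable_global.base.y1

    def test_em_dash_means_missing(self, tmp_path):
        path = tmp_path / "row.csv"
        path.write_text("name,n,q,z1,z2,y1,x1,mu,sigma,epsilon\n"
                        "demo,3,0.4170,—,0.5859,0.7570,—,2.35,3.1506,0.6364\n")
        (model,) = io.read_models_csv(path)
        assert model.n_points == 3 and model.z1 == 0.0 and model.x1 == 0.0


class TestXyz:
    def test_round_trip_exact_to_1e12(self, tmp_path, rigid4_gas_exp):
        sites = rigid4_gas_exp.to_sites()
        path = tmp_path / "mono.xyz"
        io.write_xyz(path, sites, comment="monomer")
        back = io.read_xyz(path)
        assert len(back) == len(sites)
        for a, b in zip(sites, back):
            assert a.kind == b.kind
            assert a.charge == pytest.approx(b.charge, abs=1e-12)
            assert np.allclose(a.position, b.position, atol=1e-12)

    def test_dimer_file_reevaluates_to_the_same_energy(self, tmp_path,
                                                       rigid4_gas_exp):
        state = minimize_dimer(rigid4_gas_exp, n_restarts=4, seed=0)
        path = tmp_path / "dimer.xyz"
        io.write_dimer_xyz(rigid4_gas_exp, state, path)
        sites = io.read_xyz(path)
        half = len(sites) // 2
        pos = [s.position for s in sites]
        chg = [s.charge for s in sites]
        kinds = [s.kind for s in sites]
        iO = kinds.index("oxygen")
        e = coulomb_lj_energy(pos[:half], chg[:half], iO, pos[half:], chg[half:],
                              iO, rigid4_gas_exp.lj_sigma,
                              rigid4_gas_exp.lj_epsilon / 4.184)
        assert e == pytest.approx(state.energy, abs=1e-9)


def test_pdb_names_pseudo_atoms(tmp_path, polarizable_global):
    state = minimize_dimer(polarizable_global, n_restarts=4, seed=0,
                           r_oo_fixed=2.91)
    path = tmp_path / "dimer.pdb"
    io.write_pdb(path, io.dimer_sites(polarizable_global, state))
    text = path.read_text()
    assert "HETATM" in text and "DR1" in text and text.count("DR") == 2


def test_manifest_is_valid_json_with_versions(tmp_path):
    path = tmp_path / "run.json"
    io.write_manifest(path, {"command": "demo", "seed": 3,
                             "array": np.arange(3.0)})
    data = json.loads(path.read_text())
    assert data["seed"] == 3
    assert "watermodels" in data["versions"]
    assert data["array"] == [0.0, 1.0, 2.0]


class TestConfig:
    def test_full_config(self, tmp_path):
        path = tmp_path / "run.toml"
        path.write_text(
            "[reference]\nname = 'gas_exp'\n"
            "[targets]\np_dimer = 2.68\nr_oo = 2.91\ndipole_tol = 0.002\n"
            "[optimizer]\nn_restarts = 4\nseed = 11\n"
            "[lj]\nepsilon = 0.7113\n"
        )
        cfg = load_config(path)
        assert cfg.reference.mu == 1.86
        assert cfg.targets.dipole_tol == 0.002
        assert cfg.optimizer["seed"] == 11
        assert cfg.lj["epsilon"] == 0.7113

    def test_explicit_multipoles(self, tmp_path):
        path = tmp_path / "run.toml"
        path.write_text("[reference]\nmu = 1.9\nQt = 2.5\nQ0 = 0.1\n"
                        "Omega_t = 1.9\nOmega_0 = -1.3\n")
        cfg = load_config(path)
        assert isinstance(cfg.reference, MultipoleSet)
        assert cfg.reference.Qt == 2.5
        assert cfg.targets.p_dimer == 2.68  # defaults
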