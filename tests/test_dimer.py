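"""Dimer mechanics: energy kernel identities, analytic gradients, invariances,
multi-start minimization and geometry descriptors."""

import numpy as np
import pytest

from watermodels import (
    DimerState,
    DrudeSpec,
    attach_drude,
    build_3point,
    dimer_energy,
    dimer_geometry,
    load_reference,
    minimize_dimer,
    relax_drude,
)
from watermodels.dimer import _Objective, _System, coulomb_lj_energy


IDENTITY_Q = np.array([0.0, 0.0, 0.0, 1.0])


class TestEnergyKernel:
    def test_unit_charges_at_one_angstrom(self):
        e = coulomb_lj_energy([[0, 0, 0]], [1.0], 0, [[0, 0, 1.0]], [-1.0], 0,
                              sigma=1.0, eps_kcal=0.0)
        assert e == pytest.approx(-332.0637, abs=1e-10)

    def test_lj_zero_at_sigma_and_minus_eps_at_minimum(self):
        eps = 0.25
        e = coulomb_lj_energy([[0, 0, 0]], [0.0], 0, [[0, 0, 3.2]], [0.0], 0,
                              sigma=3.2, eps_kcal=eps)
        assert e == pytest.approx(0.0, abs=1e-12)
        rmin = 2 ** (1 / 6) * 3.2
        e = coulomb_lj_energy([[0, 0, 0]], [0.0], 0, [[0, 0, rmin]], [0.0], 0,
                              sigma=3.2, eps_kcal=eps)
        assert e == pytest.approx(-eps, abs=1e-12)

    def test_overlapping_sites_raise(self):
        with pytest.raises(ValueError, match="overlapping"):
            coulomb_lj_energy([[0, 0, 0]], [1.0], 0, [[0, 0, 1e-9]], [-1.0], 0,
                              sigma=3.0, eps_kcal=0.1)

    def test_global_rotation_invariance(self, rigid4_gas_exp, rng):
        from scipy.spatial.transform import Rotation

        sysm = _System(rigid4_gas_exp)
        t = np.array([0.4, 0.8, 2.9])
        rot2 = Rotation.random(rng=rng).as_matrix()
        pos2 = sysm.pos @ rot2.T + t
        e0 = coulomb_lj_energy(sysm.pos, sysm.chg, sysm.iO, pos2, sysm.chg,
                               sysm.iO, sysm.sigma, sysm.eps_kcal)
        g = Rotation.random(rng=rng).as_matrix()
        e1 = coulomb_lj_energy(sysm.pos @ g.T, sysm.chg, sysm.iO, pos2 @ g.T,
                               sysm.chg, sysm.iO, sysm.sigma, sysm.eps_kcal)
        assert e1 == pytest.approx(e0, abs=1e-8)

    def test_swapping_molecule_labels_preserves_energy_and_roles(
            self, rigid4_gas_exp, rng):
        state = minimize_dimer(rigid4_gas_exp, n_restarts=4, seed=3)
        geo = dimer_geometry(rigid4_gas_exp, state)
        # conjugate pose: molecule 2 clamped, molecule 1 posed
        R = state.rotation_matrix
        q = state.quaternion
        q_inv = np.array([-q[0], -q[1], -q[2], q[3]])
        t_inv = -(R.T @ state.translation)
        swapped = DimerState(q_inv, t_inv)
        assert dimer_energy(rigid4_gas_exp, swapped) == pytest.approx(
            state.energy, abs=1e-9)
        geo_swapped = dimer_geometry(rigid4_gas_exp, swapped)
        assert geo_swapped.theta == pytest.approx(geo.theta, abs=1e-6)
        assert geo_swapped.phi == pytest.approx(geo.phi, abs=1e-6)
        assert geo_swapped.total_dipole == pytest.approx(geo.total_dipole, abs=1e-8)


class TestGradients:
    @pytest.mark.parametrize("key,r_fixed", [
        ("table2/gas_exp/4", None),
        ("table2/gas_exp/5", None),
        ("table2/gas_exp/3", 2.91),
        ("table3/alpha_and_mu", None),
        ("table3/alpha", 2.91),
    ])
    def test_analytic_gradient_matches_central_differences(self, key, r_fixed, rng):
        model = load_reference(key)
        obj = _Objective(_System(model), r_fixed=r_fixed)
        for _ in range(3):
            x = np.concatenate([rng.normal(size=4),
                                rng.normal(size=3) * 0.4 + [0.3, 0.5, 3.2]])
            obj.reset()
            _, g = obj(x)
            h = 3e-6
            for i in range(7):
                xp, xm = x.copy(), x.copy()
                xp[i] += h
                xm[i] -= h
                obj.reset()
                ep = obj(xp)[0]
                obj.reset()
                em = obj(xm)[0]
                fd = (ep - em) / (2 * h)
                assert g[i] == pytest.approx(fd, rel=2e-6, abs=2e-6)


class TestMinimizeDimer:
    def test_multistart_energies_agree_across_seeds(self, rigid4_gas_exp):
        e0 = minimize_dimer(rigid4_gas_exp, n_restarts=32, seed=0).energy
        e1 = minimize_dimer(rigid4_gas_exp, n_restarts=32, seed=1).energy
        assert abs(e0 - e1) < 1e-6

    def test_gradient_norm_below_tolerance(self, rigid4_gas_exp):
        state = minimize_dimer(rigid4_gas_exp, n_restarts=8, seed=0, tol=1e-6)
        assert state.diagnostics["grad_norm"] < 1e-6

    def test_same_seed_is_bitwise_reproducible(self, rigid4_gas_exp):
        a = minimize_dimer(rigid4_gas_exp, n_restarts=6, seed=5)
        b = minimize_dimer(rigid4_gas_exp, n_restarts=6, seed=5)
        assert a.energy == b.energy
        assert np.array_equal(a.translation, b.translation)

    def test_r_oo_fixed_mode_constrains_distance(self, rigid4_gas_exp):
        state = minimize_dimer(rigid4_gas_exp, n_restarts=8, seed=0, r_oo_fixed=3.1)
        geo = dimer_geometry(rigid4_gas_exp, state)
        assert geo.r_oo == pytest.approx(3.1, abs=1e-9)

    def test_global_basin_can_lie_below_hbond_basin(self):
        # the rigid 3-point layout prefers the cyclic doubly bonded dimer
        model = load_reference("table2/gas_exp/3")
        hb = minimize_dimer(model, n_restarts=16, seed=0, basin="hbond")
        glob = minimize_dimer(model, n_restarts=16, seed=0, basin="global")
        assert glob.energy < hb.energy
        assert dimer_geometry(model, glob).total_dipole == pytest.approx(0.0, abs=1e-6)
        assert dimer_geometry(model, hb).total_dipole == pytest.approx(2.68, rel=5e-3)

    def test_invalid_arguments(self, rigid4_gas_exp):
        with pytest.raises(ValueError):
            minimize_dimer(rigid4_gas_exp, n_restarts=0)
        with pytest.raises(ValueError):
            minimize_dimer(rigid4_gas_exp, basin="widest")

    def test_missing_lj_parameters_raise(self, gas_exp):
        bare = build_3point(gas_exp, 1.964)
        with pytest.raises(ValueError, match="LJ"):
            minimize_dimer(bare, n_restarts=1)


class TestDrudeMechanics:
    def test_force_balance_at_relaxed_displacements(self, polarizable_global):
        from watermodels.dimer import _assemble, _field_at

        state = minimize_dimer(polarizable_global, n_restarts=8, seed=0,
                               r_oo_fixed=2.91)
        sysm = _System(polarizable_global)
        pos1, chg1, pos2, chg2 = _assemble(sysm, state)
        qd, k = sysm.drude_q, sysm.drude_k
        # drude of molecule 1 feels the field of all molecule-2 sites
        e_loc = _field_at(pos1[-1], pos2, chg2)
        residual = 2 * k * state.drude_disp[0] - qd * e_loc
        assert np.max(np.abs(residual)) < 1e-6

    def test_zero_polarizability_reduces_to_rigid_base(self, gas_exp, rng):
        base = build_3point(gas_exp, 1.86).with_lj(3.3836, 0.7113)
        model = attach_drude(base, DrudeSpec(alpha=0.0))
        for _ in range(4):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            t = rng.normal(size=3) * 0.3 + [0.2, 0.5, 3.2]
            st = DimerState(q, t)
            assert dimer_energy(model, st) == pytest.approx(
                dimer_energy(base, st), abs=1e-12)

    def test_relax_drude_returns_converged_state(self, polarizable_global):
        st = minimize_dimer(polarizable_global, n_restarts=4, seed=2,
                            r_oo_fixed=2.91)
        fresh = relax_drude(polarizable_global,
                            DimerState(st.quaternion, st.translation))
        assert fresh.energy == pytest.approx(st.energy, abs=1e-9)
        assert np.max(np.abs(fresh.drude_disp - st.drude_disp)) < 1e-9


class TestDimerGeometry:
    def test_collinear_axes_give_zero_or_180(self, rigid4_gas_exp):
        st = DimerState(IDENTITY_Q, np.array([0.0, 0.0, 3.2]))
        geo = dimer_geometry(rigid4_gas_exp, st)
        assert geo.theta == pytest.approx(0.0, abs=1e-9)
        assert geo.phi == pytest.approx(0.0, abs=1e-9)
        # acceptor flipped by 180 degrees about y
        st = DimerState(np.array([0.0, 1.0, 0.0, 0.0]), np.array([0.0, 0.0, 3.2]))
        geo = dimer_geometry(rigid4_gas_exp, st)
        assert geo.phi == pytest.approx(180.0, abs=1e-9)

    def test_minimized_4point_matches_reference_distance_and_dipole(
            self, rigid4_gas_exp):
        st = minimize_dimer(rigid4_gas_exp, n_restarts=8, seed=0)
        geo = dimer_geometry(rigid4_gas_exp, st)
        assert geo.r_oo == pytest.approx(2.91, abs=0.01)
        assert geo.total_dipole == pytest.approx(2.68, rel=2e-3)
        assert geo.angle_error == abs(geo.theta - 57.9) + abs(geo.phi - 55.6)

    def test_energy_at_returned_state_is_recomputable(self, rigid4_gas_exp):
        st = minimize_dimer(rigid4_gas_exp, n_restarts=4, seed=1)
        assert dimer_energy(rigid4_gas_exp, st) == pytest.approx(st.energy, abs=1e-10)
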