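"""Force correctness, SHAKE, boundary restraint, and NVE integrator physics."""

import numpy as np
import pytest

from dropletmd import (
    COULOMB_K,
    EngineConfig,
    FieldSpec,
    Solute,
    TIP3P,
    boundary_force,
    build_cluster,
    compute_forces,
    init_velocities,
    run,
    solute_pair,
)
from dropletmd.engine import shake
from .conftest import hand_cluster, make_water


def _vacuum_pair(d, q1=-1.0, q2=+1.0):
    s1, s2 = solute_pair(q1, q2, d)
    return hand_cluster([], [s1, s2], radius=10.0)


class TestComputeForces:
    def test_ion_pair_closed_form(self):
        cl = _vacuum_pair(3.0)
        f, en = compute_forces(cl)
        f_coul = COULOMB_K / 9.0  # attractive at unit charges
        s6 = (3.5364 / 3.0) ** 6
        f_lj = 12 * 0.1521 / 3.0 * (s6 * s6 - s6)  # repulsive
        # net force on S2 (+x side) points toward S1 (−x)
        assert f[1, 0] == pytest.approx(-(f_coul - f_lj), rel=1e-12)
        assert f[1, 0] == pytest.approx(-34.15, abs=5e-3)
        assert f_coul == pytest.approx(36.90, abs=5e-3)
        assert f_lj == pytest.approx(2.75, abs=5e-3)
        np.testing.assert_allclose(f[0], -f[1], atol=1e-12)
        # energies consistent with closed form
        assert en["coulomb"] == pytest.approx(-COULOMB_K / 3.0, rel=1e-12)

    def test_field_on_lone_solute(self):
        cl = hand_cluster([], [Solute(charge=+1.0)], radius=5.0)
        f, _ = compute_forces(cl, FieldSpec.x(50.0))
        assert f[0] == pytest.approx([11.53, 0.0, 0.0], abs=5e-3)

    def test_newtons_third_law_sum(self, rng):
        cl = build_cluster(6.0, [Solute(charge=-1.0)], seed=8)
        f, _ = compute_forces(cl)  # no field; all oxygens inside -> no boundary
        assert np.all(np.linalg.norm(cl.oxygen_coords, axis=1) < cl.radius)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_overlap_reported(self):
        s1 = Solute(charge=0.0, position=(0.0, 0.0, 0.0))
        s2 = Solute(charge=0.0, position=(0.05, 0.0, 0.0))
        cl = hand_cluster([], [s1, s2], radius=5.0)
        with pytest.raises(ValueError, match="overlap"):
            compute_forces(cl)

    def test_force_is_negative_energy_gradient(self):
        cl = build_cluster(5.0, [Solute(charge=+1.0)], seed=12)
        # push one oxygen outside to engage the boundary term too
        cl.coords[0] *= 5.6 / np.linalg.norm(cl.coords[0])
        field = FieldSpec.x(30.0)
        f, _ = compute_forces(cl, field)
        rng = np.random.default_rng(4)
        h = 1e-5
        for idx in rng.choice(cl.n_water_atoms, size=6, replace=False):
            for k in range(3):
                plus = cl.coords.copy()
                minus = cl.coords.copy()
                plus[idx, k] += h
                minus[idx, k] -= h
                _, ep = compute_forces(cl, field, coords=plus)
                _, em = compute_forces(cl, field, coords=minus)
                num = -(ep["potential"] - em["potential"]) / (2 * h)
                assert num == pytest.approx(f[idx, k], rel=1e-5, abs=1e-7)


class TestBoundary:
    def test_outside_oxygen_pulled_inward(self):
        w = make_water([0.0, 0.0, 6.0])
        cl = hand_cluster([w], radius=5.0)
        f, e = boundary_force(cl, k=2.0)
        assert f[0] == pytest.approx([0.0, 0.0, -2.0], abs=1e-12)
        assert e == pytest.approx(0.5 * 2.0 * 1.0**2)
        np.testing.assert_array_equal(f[1:], 0.0)  # hydrogens untouched

    def test_inside_no_force(self):
        cl = hand_cluster([make_water([1.0, 0.0, 0.0])], radius=5.0)
        f, e = boundary_force(cl, k=2.0)
        assert e == 0.0
        np.testing.assert_array_equal(f, 0.0)

    def test_energy_gradient_consistency(self):
        cl = hand_cluster([make_water([0.0, 4.2, 3.9])], radius=5.0)
        f, _ = boundary_force(cl, k=2.0)
        h = 1e-6
        for k in range(3):
            plus = cl.coords.copy()
            minus = cl.coords.copy()
            plus[0, k] += h
            minus[0, k] -= h
            _, ep = boundary_force(cl, 2.0, coords=plus)
            _, em = boundary_force(cl, 2.0, coords=minus)
            assert -(ep - em) / (2 * h) == pytest.approx(f[0, k], abs=1e-6)

    def test_never_applied_to_solutes(self):
        cl = hand_cluster([], [Solute(position=(6.0, 0.0, 0.0))], radius=5.0)
        # solute deliberately outside; boundary ignores it
        f, e = boundary_force(cl, k=2.0)
        assert e == 0.0 and np.all(f == 0.0)


class TestShake:
    def test_restores_stretched_bond(self):
        cl = hand_cluster([make_water([0.0, 0.0, 0.0])], radius=5.0)
        ref = cl.coords.copy()
        pos = cl.coords.copy()
        # stretch both O-H bonds to ~1.05 Å
        for h in (1, 2):
            pos[h] = pos[0] + (pos[h] - pos[0]) * (1.05 / TIP3P.bond_oh)
        shake(pos, ref, cl)
        for h in (1, 2):
            assert np.linalg.norm(pos[h] - pos[0]) == pytest.approx(
                TIP3P.bond_oh, abs=1e-6
            )
        assert np.linalg.norm(pos[2] - pos[1]) == pytest.approx(
            TIP3P.hh_distance, abs=1e-6
        )

    def test_satisfied_geometry_unchanged(self):
        cl = hand_cluster([make_water([1.0, 2.0, 0.5])], radius=9.0)
        pos = cl.coords.copy()
        shake(pos, cl.coords.copy(), cl)
        np.testing.assert_allclose(pos, cl.coords, atol=1e-9)

    def test_residuals_during_dynamics(self):
        cl = build_cluster(6.0, [], seed=3)
        traj = run(cl, None, EngineConfig(min_steps=50, equil_time=0.2,
                                          prod_time=0.5), seed=3)
        w = traj.frames[-1, : 3 * traj.n_waters].reshape(-1, 3, 3)
        for a, b, d0 in [(0, 1, TIP3P.bond_oh), (0, 2, TIP3P.bond_oh),
                         (1, 2, TIP3P.hh_distance)]:
            r = np.linalg.norm(w[:, a] - w[:, b], axis=1)
            assert np.max(np.abs(r - d0)) < 1e-6


class TestIntegrator:
    def test_nve_energy_drift(self):
        """Total energy drift below 0.02 kcal/mol per DOF over 10 ps."""
        cl = build_cluster(10.0, [], seed=6)
        cfg = EngineConfig(min_steps=100, equil_time=2.0, prod_time=10.0)
        traj = run(cl, None, cfg, seed=6)
        log = traj.energy_log
        # linear drift over the production window, per degree of freedom
        coef = np.polyfit(log["time_ps"], log["total"], 1)
        drift = abs(coef[0]) * 10.0 / (6 * traj.n_waters)
        assert drift < 0.02

    def test_temperature_near_target(self):
        cl = build_cluster(10.0, [], seed=6)
        cfg = EngineConfig(min_steps=100, equil_time=2.0, prod_time=5.0)
        traj = run(cl, None, cfg, seed=6)
        assert traj.energy_log["temperature"].mean() == pytest.approx(300.0, abs=15.0)

    def test_time_reversibility(self):
        cl = build_cluster(5.0, [], seed=2)
        cfg = EngineConfig(precision="double")
        from dropletmd.engine import _FastForceField, minimize
        from dropletmd.model import KCAL_TO_AMU_A2_PS2

        cl = minimize(cl, None, cfg.replace(min_steps=50))
        init_velocities(cl, 300.0, seed=2)
        ff = _FastForceField(cl, FieldSpec.zero(), cfg)
        pos0 = cl.coords.copy()
        pos = cl.coords
        vel = cl.velocities
        mass = cl.masses()
        n_wa = cl.n_water_atoms
        inv_m_dt = (cfg.dt * KCAL_TO_AMU_A2_PS2 / mass[:n_wa])[:, None]

        def step():
            f = ff.forces(pos)
            vel[:n_wa] += f[:n_wa] * inv_m_dt
            ref = pos.copy()
            pos[:n_wa] += cfg.dt * vel[:n_wa]
            shake(pos, ref, cl, cfg.shake_tol)
            vel[:n_wa] = (pos[:n_wa] - ref[:n_wa]) / cfg.dt

        for _ in range(5):
            step()
        # leapfrog time mirror: the reverse of state (x_n, v_{n+1/2}) is
        # (x_{n-1}, -v_{n+1/2}), since v_{n+1/2} = (x_n - x_{n-1})/dt
        pos[:n_wa] -= cfg.dt * vel[:n_wa]
        vel[:n_wa] *= -1.0
        for _ in range(4):
            step()
        assert np.max(np.abs(pos - pos0)) < 1e-8

    def test_momentum_conservation_without_external_terms(self):
        # no field; all waters inside the radius -> boundary inactive
        cl = build_cluster(5.0, [], seed=13)
        cfg = EngineConfig(precision="double", boundary_k=0.0,
                           min_steps=50, equil_time=0.0, prod_time=0.2)
        traj = run(cl, None, cfg, seed=13)
        mass = traj.cluster.masses()[: 3 * traj.n_waters, None]
        v = traj.cluster.velocities[: 3 * traj.n_waters]
        p = (mass * v).sum(axis=0)
        assert np.linalg.norm(p) < 1e-7

    def test_fixed_solutes_never_move(self):
        s1, s2 = solute_pair(-1.0, +1.0, 3.0)
        cl = build_cluster(6.0, [s1, s2], seed=4)
        cfg = EngineConfig(min_steps=50, equil_time=0.2, prod_time=0.4)
        traj = run(cl, None, cfg, seed=4)
        for frame in traj.frames:
            np.testing.assert_array_equal(frame[-2], [-1.5, 0.0, 0.0])
            np.testing.assert_array_equal(frame[-1], [+1.5, 0.0, 0.0])

    def test_run_deterministic_given_seed(self):
        cl = build_cluster(5.0, [], seed=1)
        cfg = EngineConfig(min_steps=20, equil_time=0.1, prod_time=0.2)
        t1 = run(cl.copy(), FieldSpec.x(20.0), cfg, seed=9)
        t2 = run(cl.copy(), FieldSpec.x(20.0), cfg, seed=9)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_frame_spacing_and_zero_field_isotropy(self):
        from dropletmd import mean_dipole

        cl = build_cluster(8.0, [], seed=10)
        cfg = EngineConfig(min_steps=100, equil_time=1.0, prod_time=6.0)
        traj = run(cl, None, cfg, seed=10)
        spacing = np.diff(traj.times)
        np.testing.assert_allclose(spacing, cfg.dt * cfg.save_interval,
                                   atol=1e-12)
        # no field: mean dipole small compared to full alignment (0.4887)
        p = mean_dipole(traj, r_cut=traj.cluster.radius)
        assert abs(p.p) < 0.1

    def test_cutoff_must_cover_droplet(self):
        cl = build_cluster(5.0, [], seed=1)
        with pytest.raises(ValueError, match="cutoff"):
            run(cl, None, EngineConfig(cutoff=8.0), seed=1)
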