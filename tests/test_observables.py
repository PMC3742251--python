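"""Dipole/field observables against independent brute-force summations."""

import numpy as np
import pytest

from dropletmd import (
    COULOMB_K,
    FieldSpec,
    Solute,
    TIP3P,
    fit_polarizability,
    mean_dipole,
    mean_net_field,
    pool_profile_points,
    radial_profiles,
)
from .conftest import hand_trajectory, make_water, rotation_matrix


def brute_dipole_sum(frames, n_waters, r_cut):
    """Independent Eq-style evaluation: loop every frame/water/atom."""
    q = [TIP3P.q_o, TIP3P.q_h, TIP3P.q_h]
    total = np.zeros(3)
    count = 0
    for frame in frames:
        for m in range(n_waters):
            atoms = frame[3 * m : 3 * m + 3]
            if np.linalg.norm(atoms[0]) <= r_cut:
                count += 1
                for i in range(3):
                    total += q[i] * (atoms[i] - atoms[0])
    return total, count


def brute_net_field(frames, n_waters, charges, mol, r_cut, e_ext):
    """Field at qualifying oxygens from atoms of all other molecules."""
    total = np.zeros(3)
    count = 0
    for frame in frames:
        for m in range(n_waters):
            o = frame[3 * m]
            if np.linalg.norm(o) > r_cut:
                continue
            count += 1
            for j in range(frame.shape[0]):
                if mol[j] == m:
                    continue
                rv = o - frame[j]
                r = np.linalg.norm(rv)
                total += COULOMB_K * charges[j] * rv / r**3
    return total / count + e_ext, count


class TestMeanDipole:
    def test_single_aligned_water(self):
        traj = hand_trajectory([make_water([0, 0, 0])],
                               fieldspec=FieldSpec.x(1.0))
        pt = mean_dipole(traj, r_cut=5.0)
        assert pt.p == pytest.approx(TIP3P.dipole_magnitude, rel=1e-12)
        assert pt.n == 1

    def test_matches_brute_force(self, rng):
        waters = [
            make_water(rng.uniform(-6, 6, 3),
                       rotation_matrix(rng.normal(size=3), rng.uniform(0, 7)))
            for _ in range(5)
        ]
        traj = hand_trajectory(waters, fieldspec=FieldSpec.x(10.0), n_frames=3)
        pt = mean_dipole(traj, r_cut=6.0)
        ref, count = brute_dipole_sum(traj.frames, 5, 6.0)
        assert pt.n == count
        np.testing.assert_allclose(pt.p_vector, ref / count, rtol=1e-10)

    def test_count_monotone_in_r_cut(self, rng):
        waters = [make_water([0.0, 0.0, 0.0])]
        waters += [make_water(rng.uniform(-8, 8, 3)) for _ in range(9)]
        traj = hand_trajectory(waters)
        counts = [mean_dipole(traj, r_cut=r).n
                  for r in (5.0, 8.0, 12.0, 15.0)]
        assert counts == sorted(counts)

    def test_saturation_bound(self, rng):
        # |p| can never exceed the rigid-geometry dipole magnitude
        waters = [
            make_water(rng.uniform(-4, 4, 3),
                       rotation_matrix(rng.normal(size=3), rng.uniform(0, 7)))
            for _ in range(8)
        ]
        traj = hand_trajectory(waters, n_frames=2)
        pt = mean_dipole(traj, r_cut=10.0)
        assert np.linalg.norm(pt.p_vector) <= TIP3P.dipole_magnitude + 1e-12

    def test_no_qualifying_waters(self):
        traj = hand_trajectory([make_water([8.0, 0, 0])])
        with pytest.raises(ValueError, match="r_cut"):
            mean_dipole(traj, r_cut=2.0)


class TestMeanNetField:
    def test_lone_water_zero_field(self):
        traj = hand_trajectory([make_water([0, 0, 0])])
        pt = mean_net_field(traj, r_cut=5.0)
        assert pt.e_net == pytest.approx(0.0, abs=1e-12)

    def test_lone_water_pure_conversion(self):
        traj = hand_trajectory([make_water([0, 0, 0])],
                               fieldspec=FieldSpec.x(50.0))
        pt = mean_net_field(traj, r_cut=5.0)
        assert pt.e_net == pytest.approx(11.53, abs=5e-3)

    def test_matches_brute_force_with_solute(self, rng):
        waters = [
            make_water(rng.uniform(-5, 5, 3),
                       rotation_matrix(rng.normal(size=3), rng.uniform(0, 7)))
            for _ in range(4)
        ]
        sol = Solute(charge=-1.0, position=(1.0, 2.0, 0.0))
        field = FieldSpec.y(25.0)
        traj = hand_trajectory(waters, [sol], fieldspec=field, n_frames=2)
        pt = mean_net_field(traj, r_cut=6.0)
        cl = traj.cluster
        ref, count = brute_net_field(
            traj.frames, 4, cl.charges(), cl.mol_ids(), 6.0,
            field.vector_kcal,
        )
        assert pt.n == count
        np.testing.assert_allclose(pt.e_net_vector, ref, rtol=1e-10)


class TestRadialProfiles:
    def test_radially_oriented_water(self):
        # dipole pointing outward at r = 5 along +x
        w = make_water([5.0, 0.0, 0.0])  # template bisector along +x
        traj = hand_trajectory([w], [Solute(charge=+1.0)])
        prof = radial_profiles(traj)
        k = int(5.0 / prof.dr)
        assert prof.n[k] == 1
        assert prof.p[k] == pytest.approx(TIP3P.dipole_magnitude, rel=1e-10)

    def test_solute_point_charge_term(self):
        # lone water: field at its oxygen is the solute term only
        w = make_water([5.0, 0.0, 0.0])
        traj = hand_trajectory([w], [Solute(charge=+1.0)])
        prof = radial_profiles(traj)
        k = int(5.0 / prof.dr)
        assert prof.e_net[k] == pytest.approx(COULOMB_K / 25.0, rel=1e-12)
        assert prof.e_net[k] == pytest.approx(13.28, abs=5e-3)

    def test_empty_bins_are_nan(self):
        traj = hand_trajectory([make_water([5.0, 0, 0])], [Solute()])
        prof = radial_profiles(traj)
        assert np.isnan(prof.p[0])
        assert prof.n[0] == 0

    def test_two_waters_match_brute_force(self):
        w1 = make_water([4.0, 0.0, 0.0])
        w2 = make_water([0.0, 6.0, 0.0],
                        rotation_matrix([0, 0, 1.0], 0.7))
        traj = hand_trajectory([w1, w2], [Solute(charge=-0.6)])
        prof = radial_profiles(traj)
        # independent evaluation for the water at r = 4
        q = traj.cluster.charges()
        frame = traj.frames[0]
        o = frame[0]
        u = o / np.linalg.norm(o)
        e = COULOMB_K * (-0.6) / 16.0
        for j in range(3, 6):  # atoms of the other water
            rv = o - frame[j]
            e += COULOMB_K * q[j] * (rv @ u) / np.linalg.norm(rv) ** 3
        k = int(4.0 / prof.dr)
        assert prof.e_net[k] == pytest.approx(e, rel=1e-10)

    def test_requires_central_solute(self):
        traj = hand_trajectory([make_water([3.0, 0, 0])])
        with pytest.raises(ValueError, match="exactly one"):
            radial_profiles(traj)
        traj2 = hand_trajectory([make_water([3.0, 0, 0])],
                                [Solute(position=(1.0, 0, 0))])
        with pytest.raises(ValueError, match="origin"):
            radial_profiles(traj2)


class TestFitPolarizability:
    def test_exact_linear(self):
        e = np.linspace(-20, 20, 11)
        p = 0.0124 * e + 0.003
        assert fit_polarizability(e, p) == pytest.approx(0.0124, rel=1e-12)

    def test_window_excludes_saturated_region(self):
        e = np.concatenate([np.linspace(-20, 20, 21), np.linspace(30, 90, 7)])
        p = np.where(np.abs(e) < 25, 0.01 * e, np.sign(e) * 0.45)
        assert fit_polarizability(e, p, window=25.0) == pytest.approx(
            0.01, rel=1e-12
        )

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_polarizability(np.array([40.0, 50.0]), np.array([0.4, 0.42]))

    def test_pooling_skips_empty_bins(self):
        from dropletmd.observables import RadialProfile

        prof = RadialProfile(
            r=np.array([0.05, 0.15, 0.25]),
            p=np.array([np.nan, 0.1, 0.2]),
            e_net=np.array([np.nan, 10.0, 20.0]),
            n=np.array([0, 3, 5]),
            dr=0.1,
            solute_charge=1.0,
        )
        e, p, w = pool_profile_points([prof, prof])
        assert len(e) == 4
        assert fit_polarizability(e, p, w) == pytest.approx(0.01, rel=1e-12)
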