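"""Superposition, axis-angle decomposition, kinks, distances, interfaces."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from rnapconf.errors import (
    InsufficientAtomsError,
    NotARotationError,
    SelectionError,
)
from rnapconf.geometry import (
    AxisAngle,
    axis_angle_decompose,
    axis_angle_to_matrix,
    domain_rotation,
    interface_area,
    kink_angle,
    min_distance,
    pair_common_atoms,
    rmsd_between,
    superpose,
    superpose_quaternion,
)
from rnapconf.structio import Atom, AtomModel, parse_selection
from rnapconf.synthetic import (
    make_ideal_helix,
    make_kinked_helix,
    make_two_domain_model,
)


def point_atom(chain, resnum, xyz, element="C", name="X"):
    return Atom(chain, resnum, "", "UNK", name, element, tuple(map(float, xyz)))


unit_axes = st.tuples(
    st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1)
).map(np.array).filter(lambda v: np.linalg.norm(v) > 1e-3)


class TestSuperpose:
    def test_identity_on_equal_clouds(self, rng):
        X = rng.normal(size=(40, 3))
        res = superpose(X, X)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_constructed_rotation(self, rng):
        X = rng.normal(size=(50, 3)) * 10
        R = axis_angle_to_matrix([0, 0, 1], 37.0)
        Y = X @ R.T + np.array([5.0, -3.0, 2.0])
        res = superpose(Y, X)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        aa = axis_angle_decompose(res.transform.rotation)
        assert aa.angle_deg == pytest.approx(37.0, abs=1e-6)

    def test_never_returns_a_reflection(self, rng):
        # near-planar cloud where the unguarded SVD solution would reflect
        X = rng.normal(size=(30, 3))
        X[:, 2] *= 1e-9
        Y = -X
        res = superpose(X, Y)
        assert np.linalg.det(res.transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_quaternion_oracle_on_noisy_clouds(self, rng):
        for _ in range(200):
            X = rng.normal(size=(50, 3)) * 8
            R = Rotation.random(random_state=rng).as_matrix()
            Y = X @ R.T + rng.normal(size=3) * 10 + rng.normal(size=(50, 3)) * 0.1
            svd = superpose(Y, X)
            quat = superpose_quaternion(Y, X)
            assert abs(svd.rmsd - quat.rmsd) < 1e-9

    def test_rmsd_invariant_under_rigid_motion_of_inputs(self, rng):
        X = rng.normal(size=(40, 3)) * 5
        Y = X + rng.normal(size=(40, 3)) * 0.3
        base = superpose(X, Y).rmsd
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.normal(size=3) * 20
        assert superpose(X @ R.T + t, Y).rmsd == pytest.approx(base, abs=1e-9)
        assert superpose(X, Y @ R.T + t).rmsd == pytest.approx(base, abs=1e-9)

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientAtomsError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestAxisAngle:
    def test_identity_flagged_unreliable(self):
        aa = axis_angle_decompose(np.eye(3))
        assert aa.angle_deg == pytest.approx(0.0)
        assert not aa.axis_reliable

    def test_quarter_turn_about_z(self):
        aa = axis_angle_decompose(axis_angle_to_matrix([0, 0, 1], 90.0))
        assert aa.angle_deg == pytest.approx(90.0, abs=1e-9)
        np.testing.assert_allclose(aa.axis, [0, 0, 1], atol=1e-9)

    def test_agrees_with_quaternion_extraction_oracle(self, rng):
        for _ in range(2000):
            rot = Rotation.random(random_state=rng)
            aa = axis_angle_decompose(rot.as_matrix())
            expected = math.degrees(np.linalg.norm(rot.as_rotvec()))
            assert aa.angle_deg == pytest.approx(expected, abs=1e-9)

    @given(unit_axes, st.floats(0.5, 179.5))
    def test_round_trip_reproduces_matrix(self, axis, angle):
        axis = axis / np.linalg.norm(axis)
        R = axis_angle_to_matrix(axis, angle)
        aa = axis_angle_decompose(R)
        np.testing.assert_allclose(
            axis_angle_to_matrix(aa.axis, aa.angle_deg), R, atol=1e-6
        )

    def test_near_180_branch_is_stable(self):
        for axis in ([1, 0, 0], [0, 1, 0], [0.6, -0.48, 0.64]):
            R = axis_angle_to_matrix(axis, 179.95)
            aa = axis_angle_decompose(R)
            assert aa.angle_deg == pytest.approx(179.95, abs=1e-6)
            np.testing.assert_allclose(
                axis_angle_to_matrix(aa.axis, aa.angle_deg), R, atol=1e-6
            )

    def test_non_rotation_rejected(self):
        with pytest.raises(NotARotationError):
            axis_angle_decompose(np.diag([1.0, 1.0, -1.0]))


class TestDomainRotation:
    CORE = parse_selection("A:1-60")
    DOMAIN = parse_selection("B:1-60")

    @pytest.mark.parametrize("angle", [1.0, 4.5, 18.0, 121.0])
    def test_recovers_applied_angle_exactly(self, angle):
        axis = np.array([0.2, -0.6, 0.75])
        ref, moved, truth = make_two_domain_model(
            60, 60, AxisAngle(axis, angle), seed=7
        )
        aa = domain_rotation(ref, moved, self.CORE, self.DOMAIN)
        assert aa.angle_deg == pytest.approx(angle, abs=1e-6)
        assert abs(np.dot(aa.axis, truth.parameters["axis"])) >= 0.999999

    def test_small_rotation_with_noise_within_tolerance(self):
        # Si3-sized construct: 188 Cα in the rotating domain, 0.2 Å noise
        errors = []
        for seed in range(40):
            ref, moved, _ = make_two_domain_model(
                200, 188, AxisAngle(np.array([0, 0, 1.0]), 4.5), noise_sd=0.2,
                seed=seed, spread=12.0,
            )
            aa = domain_rotation(
                ref, moved, parse_selection("A:1-200"), parse_selection("B:1-188")
            )
            errors.append(abs(aa.angle_deg - 4.5))
        assert max(errors) < 0.3

    def test_zero_rotation_flags_axis(self):
        ref, moved, _ = make_two_domain_model(
            30, 30, AxisAngle(np.array([0, 0, 1.0]), 0.0), seed=2
        )
        aa = domain_rotation(
            ref, moved, parse_selection("A:1-30"), parse_selection("B:1-30")
        )
        assert aa.angle_deg < 0.1
        assert not aa.axis_reliable

    def test_pivot_sits_on_rotation_axis(self):
        axis = np.array([0.0, 1.0, 0.0])
        ref, moved, truth = make_two_domain_model(
            40, 40, AxisAngle(axis, 30.0), seed=5
        )
        aa = domain_rotation(
            ref, moved, parse_selection("A:1-40"), parse_selection("B:1-40")
        )
        # the true pivot must be on the recovered axis: its offset from the
        # recovered pivot has no component perpendicular to the axis
        d = truth.parameters["pivot"] - aa.pivot_point
        perp = d - np.dot(d, aa.axis) * aa.axis
        assert np.linalg.norm(perp) < 1e-6


class TestPairing:
    def test_identical_models_pair_every_ca(self):
        helix = make_ideal_helix(30)
        _, _, n, unmatched = pair_common_atoms(helix, helix)
        assert n == 30 and unmatched == []

    def test_missing_residues_are_skipped(self):
        helix = make_ideal_helix(30)
        pruned = AtomModel(
            tuple(a for a in helix.atoms if not 5 <= a.residue_number <= 10)
        )
        _, _, n, unmatched = pair_common_atoms(helix, pruned)
        assert n == 24
        assert {r[1] for r in unmatched} == set(range(5, 11))

    def test_rmsd_between_self_is_zero_and_symmetric(self, rng):
        helix = make_ideal_helix(40)
        jitter = AtomModel(
            tuple(
                Atom(
                    a.chain_id, a.residue_number, a.insertion_code, a.residue_name,
                    a.atom_name, a.element,
                    tuple(np.array(a.position) + rng.normal(scale=0.3, size=3)),
                )
                for a in helix.atoms
            )
        )
        assert rmsd_between(helix, helix)[0] == pytest.approx(0.0, abs=1e-12)
        ab, _ = rmsd_between(helix, jitter)
        ba, _ = rmsd_between(jitter, helix)
        assert ab == pytest.approx(ba, abs=1e-9)

    def test_exclude_removes_residues_from_pairing(self):
        helix = make_ideal_helix(30)
        _, n = rmsd_between(helix, helix, exclude=parse_selection("A:1-10"))
        assert n == 20


class TestKink:
    def test_straight_helix_is_straight(self):
        res = kink_angle(make_ideal_helix(30), parse_selection("A:1-30"), 15)
        assert res.angle_deg < 2.0

    @pytest.mark.parametrize("angle", [25.0, 29.0, 30.0, 150.0])
    def test_constructed_kink_recovered(self, angle):
        model, _ = make_kinked_helix(30, 15, angle)
        res = kink_angle(model, parse_selection("A:1-30"), 15)
        assert res.angle_deg == pytest.approx(angle, abs=1.0)

    def test_too_short_flank_raises(self):
        model, _ = make_kinked_helix(30, 15, 20.0)
        with pytest.raises(InsufficientAtomsError):
            kink_angle(model, parse_selection("A:11-19"), 15)

    def test_missing_kink_residue_raises(self):
        with pytest.raises(SelectionError):
            kink_angle(make_ideal_helix(30), parse_selection("A:1-30"), 99)


class TestDistance:
    def test_three_four_five_triangle(self):
        model = AtomModel(
            (point_atom("A", 1, (0, 0, 0)), point_atom("B", 1, (3, 4, 0)))
        )
        d, (a, b) = min_distance(model, parse_selection("A:1"), parse_selection("B:1"))
        assert d == pytest.approx(5.0)
        assert (a.chain_id, b.chain_id) == ("A", "B")

    def test_matches_brute_force_on_random_sets(self, rng):
        atoms_a = tuple(
            point_atom("A", i + 1, xyz) for i, xyz in enumerate(rng.normal(size=(50, 3)) * 20)
        )
        atoms_b = tuple(
            point_atom("B", i + 1, xyz) for i, xyz in enumerate(rng.normal(size=(60, 3)) * 20)
        )
        model = AtomModel(atoms_a + atoms_b)
        d, _ = min_distance(model, parse_selection("A:1-50"), parse_selection("B:1-60"))
        brute = min(
            np.linalg.norm(np.array(p.position) - np.array(q.position))
            for p in atoms_a
            for q in atoms_b
        )
        assert d == pytest.approx(brute, abs=1e-12)

    def test_empty_selection_raises(self):
        model = AtomModel((point_atom("A", 1, (0, 0, 0)),))
        with pytest.raises(SelectionError):
            min_distance(model, parse_selection("A:1"), parse_selection("Z:1"))


class TestInterfaceArea:
    RADII = {"C": 1.7}

    def sphere_pair(self, separation):
        return AtomModel(
            (point_atom("A", 1, (0, 0, 0)), point_atom("B", 1, (separation, 0, 0)))
        )

    def test_far_apart_selections_bury_nothing(self):
        model = self.sphere_pair(50.0)
        area = interface_area(
            model, parse_selection("A:1"), parse_selection("B:1"), radii=self.RADII
        )
        assert area == 0.0

    def test_two_sphere_overlap_matches_spherical_cap(self):
        # centers 2 Å apart, radius 1.7 + probe 1.4: buried area per side is
        # the spherical cap 2πR(R − d/2) of the extended sphere R = 3.1 Å
        d = 2.0
        R = 1.7 + 1.4
        exact = 2 * math.pi * R * (R - d / 2)
        model = self.sphere_pair(d)
        area = interface_area(
            model, parse_selection("A:1"), parse_selection("B:1"), radii=self.RADII
        )
        assert area == pytest.approx(exact, rel=0.02)

    def test_monotone_decrease_with_separation(self):
        seps = [2.0, 3.0, 4.0, 5.0, 8.0]
        areas = [
            interface_area(
                self.sphere_pair(s),
                parse_selection("A:1"),
                parse_selection("B:1"),
                radii=self.RADII,
            )
            for s in seps
        ]
        assert all(x >= y for x, y in zip(areas, areas[1:]))
        assert areas[-1] == 0.0

    def test_overlapping_selections_rejected(self):
        model = self.sphere_pair(2.0)
        with pytest.raises(SelectionError):
            interface_area(model, parse_selection("A:1"), parse_selection("A:1"))
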