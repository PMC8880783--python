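"""Superposition, domain-rotation recovery and state-comparison gating."""

import numpy as np
import pytest

import cofnet as cn
from cofnet.conformation import kabsch, rotation_angle_axis
from cofnet.errors import DegenerateGeometryError, PairingError
from cofnet.synthetic import _axis_angle_matrix


def _random_points(rng, n=40, spread=8.0):
    return rng.normal(scale=spread, size=(n, 3))


class TestKabsch:
    def test_identity_transform(self):
        rng = np.random.default_rng(0)
        P = _random_points(rng)
        sup = kabsch(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(1)
        P = _random_points(rng)
        R = _axis_angle_matrix(np.array([1.0, 2.0, -0.5]), 0.8)
        t = np.array([4.0, -2.0, 9.0])
        sup = kabsch(P, P @ R.T + t)
        assert np.allclose(sup.rotation, R, atol=1e-9)
        assert np.allclose(sup.translation, t, atol=1e-8)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotation_always_proper(self):
        rng = np.random.default_rng(2)
        P = _random_points(rng)
        mirrored = P * np.array([-1.0, 1.0, 1.0])   # reflection, not rotation
        sup = kabsch(P, mirrored)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        assert sup.rmsd > 0.5

    def test_orthonormality(self):
        rng = np.random.default_rng(3)
        sup = kabsch(_random_points(rng), _random_points(rng))
        assert np.allclose(sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-9)

    def test_agrees_with_scipy_align_vectors(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(4)
        P, Q = _random_points(rng), _random_points(rng)
        sup = kabsch(P, Q)
        ref, _ = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert np.allclose(sup.rotation, ref.as_matrix(), atol=1e-8)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch(line, line)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_rmsd_invariant_under_common_rigid_motion(self):
        rng = np.random.default_rng(5)
        P, Q = _random_points(rng), _random_points(rng)
        base = kabsch(P, Q).rmsd
        R = _axis_angle_matrix(np.array([0.2, 1.0, 0.7]), 1.2)
        t = np.array([-3.0, 8.0, 1.5])
        moved = kabsch(P @ R.T + t, Q @ R.T + t).rmsd
        assert moved == pytest.approx(base, abs=1e-9)


class TestSuperpose:
    def test_pairing_by_identity(self, pb_structure):
        sup = cn.superpose(pb_structure, pb_structure, "chain B")
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert sup.n_pairs == len(cn.select(pb_structure, "chain B"))

    def test_mismatched_selections_raise(self, pb_structure):
        with pytest.raises(PairingError):
            cn.superpose(pb_structure, pb_structure,
                         "chain B", mobile_selection="chain A")


class TestDomainRotation:
    AXIS = np.array([0.3, -0.5, 1.0]) / np.linalg.norm([0.3, -0.5, 1.0])

    @pytest.mark.parametrize("angle", [5.0, 24.0, 90.0, 179.0])
    def test_noiseless_recovery_exact(self, pb_structure, angle):
        rotated = cn.make_rotated_state(pb_structure, "chain C", angle,
                                        self.AXIS, pivot=(2.0, -1.0, 3.0))
        motion = cn.domain_rotation(pb_structure, rotated,
                                    core="not chain C", domain="chain C")
        assert motion.angle == pytest.approx(angle, abs=1e-6)
        assert motion.core_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_angle_symmetric_between_states(self, pb_structure):
        rotated = cn.make_rotated_state(pb_structure, "chain C", 24.0,
                                        self.AXIS, pivot=(0, 0, 0))
        fwd = cn.domain_rotation(pb_structure, rotated, "not chain C", "chain C")
        rev = cn.domain_rotation(rotated, pb_structure, "not chain C", "chain C")
        assert fwd.angle == pytest.approx(rev.angle, abs=1e-9)

    def test_zero_motion(self, pb_structure):
        motion = cn.domain_rotation(pb_structure, pb_structure,
                                    "not chain C", "chain C")
        # arccos near +1 amplifies float noise to ~1e-6 degrees
        assert motion.angle == pytest.approx(0.0, abs=1e-5)

    def test_recovery_under_coordinate_noise(self):
        # graceful degradation: 0.2 Å Gaussian noise must stay within 0.5 deg
        # on a protein-sized domain, and error should grow with sigma
        from dataclasses import replace

        from conftest import two_domain_structure
        base = two_domain_structure(seed=17)
        rng = np.random.default_rng(17)
        rotated = cn.make_rotated_state(base, "chain D", 24.0,
                                        self.AXIS, pivot=(25.0, 0.0, 0.0))
        errors = []
        for sigma in (0.05, 0.2, 1.5):
            noisy = cn.Structure(atoms=[
                replace(a, position=a.position + rng.normal(scale=sigma, size=3))
                for a in rotated.atoms])
            motion = cn.domain_rotation(base, noisy, "chain E", "chain D")
            errors.append(abs(motion.angle - 24.0))
        assert errors[1] <= 0.5
        assert errors[0] <= errors[2]

    def test_translation_along_axis_nonnegative(self, pb_structure):
        rotated = cn.make_rotated_state(pb_structure, "chain C", 24.0,
                                        self.AXIS, pivot=(5.0, 5.0, 5.0))
        motion = cn.domain_rotation(pb_structure, rotated, "not chain C", "chain C")
        assert motion.translation_along_axis >= 0.0

    def test_angle_axis_roundtrip(self):
        for angle in (1e-3, 30.0, 120.0, 179.5):
            axis = np.array([1.0, -2.0, 0.5])
            axis = axis / np.linalg.norm(axis)
            R = _axis_angle_matrix(axis, np.radians(angle))
            got_angle, got_axis = rotation_angle_axis(R)
            assert got_angle == pytest.approx(angle, abs=1e-6)
            assert abs(np.dot(got_axis, axis)) == pytest.approx(1.0, abs=1e-6)


class TestCompareStates:
    def test_apo_to_pb_gating(self, apo_cofactors, pb_cofactors):
        cmp_result = cn.compare_states(apo_cofactors, pb_cofactors,
                                       [("C1", "B2")], tau=14,
                                       state_names=("apo", "PB"))
        row = cmp_result.rows[0]
        assert row.distance_state_a == pytest.approx(19.0, abs=0.1)
        assert row.distance_state_b == pytest.approx(13.4, abs=0.1)
        assert row.crossed_threshold

    def test_br_c1_fmn_not_yet_within_range(self, br_cofactors):
        by = {c.label: c for c in br_cofactors}
        d, _ = cn.edge_distance(by["C1"], by["FMN"])
        assert d == pytest.approx(15.5, abs=0.1)
        assert d > 14.0

    def test_identical_states_no_deltas(self, pb_cofactors):
        cmp_result = cn.compare_states(pb_cofactors, pb_cofactors,
                                       [("C1", "B2"), ("FMN", "B1")], tau=14)
        assert all(r.delta == 0.0 and not r.crossed_threshold
                   for r in cmp_result.rows)

    def test_swap_negates_deltas(self, apo_cofactors, pb_cofactors):
        pairs = [("C1", "B2"), ("B2", "B3"), ("A1", "A2")]
        fwd = cn.compare_states(apo_cofactors, pb_cofactors, pairs, tau=14)
        rev = cn.compare_states(pb_cofactors, apo_cofactors, pairs, tau=14)
        for f, r in zip(fwd.rows, rev.rows):
            assert f.delta == pytest.approx(-r.delta, abs=1e-12)
            assert f.crossed_threshold == r.crossed_threshold

    def test_missing_label_names_state(self, apo_cofactors, pb_cofactors):
        with pytest.raises(KeyError, match="FMN"):
            cn.compare_states(apo_cofactors, pb_cofactors, [("C1", "FMN")])
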