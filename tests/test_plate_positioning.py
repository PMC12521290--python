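"""Rigid transforms, landmark alignment, constrained refinement, screws."""

import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from platefit.plate_positioning import (
    PositioningConfig,
    RigidTransform,
    check_screws,
    evaluate_placement,
    initial_alignment,
    kabsch,
    refine_position,
)
from platefit.synthetic_anatomy import (
    FemurModel,
    FemurParams,
    Screw,
    make_femur,
)
from platefit.mesh_core import TriangleMesh


class TestRigidTransform:
    def test_compose_and_inverse(self):
        rng = np.random.default_rng(0)
        r = Rotation.random(random_state=1).as_matrix()
        t = RigidTransform(r, rng.normal(size=3))
        pts = rng.normal(size=(5, 3))
        round_trip = t.inverse().apply(t.apply(pts))
        np.testing.assert_allclose(round_trip, pts, atol=1e-12)
        combo = t.compose(t.inverse())
        np.testing.assert_allclose(combo.as_matrix(), np.eye(4), atol=1e-12)

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestKabsch:
    def test_identity_for_identical_point_sets(self):
        pts = np.array([[0, 0, 0], [10, 0, 0], [0, 5, 8.0]])
        t = kabsch(pts, pts)
        np.testing.assert_allclose(t.as_matrix(), np.eye(4), atol=1e-9)

    def test_recovers_known_rotation(self):
        rot = Rotation.from_euler("z", 15, degrees=True).as_matrix()
        src = np.array([[1, 0, 0], [0, 2, 0], [0, 0, 3.0], [1, 1, 1.0]])
        dst = src @ rot.T + np.array([4.0, -2.0, 7.0])
        t = kabsch(src, dst)
        np.testing.assert_allclose(t.rotation, rot, atol=1e-9)
        np.testing.assert_allclose(t.apply(src), dst, atol=1e-9)

    def test_least_squares_never_increases_rms(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            src = rng.normal(size=(4, 3)) * 10
            dst = src + rng.normal(size=(4, 3))  # noisy correspondences
            t = kabsch(src, dst)
            before = np.sqrt(((src - dst) ** 2).sum(axis=1).mean())
            after = np.sqrt(((t.apply(src) - dst) ** 2).sum(axis=1).mean())
            assert after <= before + 1e-12


class TestInitialAlignment:
    def test_near_identity_for_template_matched_bone(self, plate11):
        bone = make_femur(FemurParams(r_bow=940.0, diaphysis_length=400.0))
        t = initial_alignment(plate11, bone)
        # correspondences quantised to mesh vertices -> small but not zero
        assert np.abs(t.rotation - np.eye(3)).max() < 0.01
        assert np.linalg.norm(t.translation) < 2.0

    def test_recovers_pre_rotation(self, plate11, matched_femur):
        base = initial_alignment(plate11, matched_femur)
        rot = Rotation.from_euler("x", 15, degrees=True).as_matrix()
        pre = RigidTransform(rot, np.array([3.0, -1.0, 2.0]))
        # moving the bone by `pre` must move the alignment identically
        moved = _transform_bone(matched_femur, pre)
        t = initial_alignment(plate11, moved)
        expected = pre.compose(base)
        probe = plate11.anchors["contact_shaft"]
        np.testing.assert_allclose(t.apply(probe), expected.apply(probe),
                                   atol=1.5)  # vertex-snap quantisation

    def test_missing_landmark_raises(self, plate11, matched_femur):
        from platefit.errors import LandmarkError
        broken = copy.copy(matched_femur)
        broken.landmarks = {
            k: v for k, v in matched_femur.landmarks.items()
            if k != "distal_anterior_contact"}
        with pytest.raises(LandmarkError):
            initial_alignment(plate11, broken)


def _transform_bone(bone: FemurModel, t: RigidTransform) -> FemurModel:
    moved = copy.copy(bone)
    moved.outer = TriangleMesh.from_arrays(
        t.apply(bone.outer.vertices), bone.outer.faces, name=bone.outer.name)
    moved.inner = TriangleMesh.from_arrays(
        t.apply(bone.inner.vertices), bone.inner.faces, name=bone.inner.name)
    moved.landmarks = {k: t.apply(np.asarray(v))
                       for k, v in bone.landmarks.items()}
    return moved


@pytest.fixture(scope="module")
def matched_positioning(plate11, matched_femur):
    init = initial_alignment(plate11, matched_femur)
    return refine_position(plate11, matched_femur, init)


class TestRefinePosition:
    def test_feasible_pair_converges(self, matched_positioning):
        res = matched_positioning
        assert res.converged
        assert all(v <= 0.2 for v in res.contact_zones.values())
        assert res.penetration_count == 0
        assert res.screw_checks["fossa_clear"]
        assert res.screw_checks["proximal_screw_in_canal"]

    def test_recovers_from_translation_perturbation(self, plate11,
                                                    matched_femur):
        init = initial_alignment(plate11, matched_femur)
        perturbed = RigidTransform(np.eye(3),
                                   np.array([1.2, 1.2, 0.8])).compose(init)
        res = refine_position(plate11, matched_femur, perturbed)
        assert res.converged
        assert res.penetration_count == 0

    def test_penalty_pushes_penetrating_start_out(self, plate11,
                                                  matched_femur):
        init = initial_alignment(plate11, matched_femur)
        pressed = RigidTransform(np.eye(3),
                                 np.array([0.0, -0.5, 0.0])).compose(init)
        res = refine_position(plate11, matched_femur, pressed)
        assert res.penetration_count == 0

    def test_infeasible_bow_mismatch_reports_nonconvergence(self, plate11):
        bone = make_femur(FemurParams(r_bow=500.0, diaphysis_length=365.0))
        init = initial_alignment(plate11, bone)
        res = refine_position(plate11, bone, init)
        assert not res.converged

    def test_objective_history_monotone_nonincreasing(self, plate11):
        bone = make_femur(FemurParams(r_bow=880.0, diaphysis_length=365.0))
        init = initial_alignment(plate11, bone)
        res = refine_position(plate11, bone, init)
        hist = np.array(res.history)
        assert len(hist) >= 1
        assert np.all(np.diff(hist) <= 1e-12)

    def test_feasibility_reproducible_post_hoc(self, plate11, matched_femur,
                                               matched_positioning):
        re_eval = evaluate_placement(plate11, matched_femur,
                                     matched_positioning.transform)
        assert re_eval.converged == matched_positioning.converged
        for zone, v in matched_positioning.contact_zones.items():
            assert re_eval.contact_zones[zone] == pytest.approx(v, abs=1e-9)

    def test_equivariance_under_joint_rigid_motion(self, plate11,
                                                   matched_femur,
                                                   matched_positioning):
        pre = RigidTransform(
            Rotation.from_euler("zyx", [20, -10, 35], degrees=True).as_matrix(),
            np.array([15.0, -40.0, 60.0]))
        moved = _transform_bone(matched_femur, pre)
        init = initial_alignment(plate11, moved)
        res = refine_position(plate11, moved, init)
        assert res.converged
        probe = np.array([plate11.anchors["contact_anterior"],
                          plate11.anchors["proximal_tip"]])
        a = res.transform.apply(probe)
        b = pre.apply(matched_positioning.transform.apply(probe))
        np.testing.assert_allclose(a, b, atol=1e-6)


class TestCheckScrews:
    def test_screw_through_canal_centre(self, plate11, matched_femur,
                                        matched_positioning):
        checks = check_screws(plate11, matched_femur,
                              matched_positioning.transform)
        assert checks["proximal_screw_in_canal"]
        assert checks["fossa_clear"]

    def test_screw_aimed_at_fossa_detected(self, plate11, matched_femur,
                                           matched_positioning):
        t = matched_positioning.transform
        fossa = np.atleast_2d(
            matched_femur.landmarks["intercondylar_fossa_region"])[0]
        # construct a screw whose segment passes through a fossa point,
        # expressed back in the plate frame
        origin_w = fossa + np.array([0.0, 30.0, 0.0])
        direction_w = (fossa - origin_w) / np.linalg.norm(fossa - origin_w)
        inv = t.inverse()
        bad = copy.copy(plate11)
        bad.screws = list(plate11.screws) + [Screw(
            origin=inv.apply(origin_w),
            direction=inv.rotation @ direction_w, length=60.0)]
        checks = check_screws(bad, matched_femur, t)
        assert not checks["fossa_clear"]

    def test_matches_bruteforce_segment_distance(self, plate11,
                                                 matched_femur,
                                                 matched_positioning):
        t = matched_positioning.transform
        fossa = np.atleast_2d(np.asarray(
            matched_femur.landmarks["intercondylar_fossa_region"], float))
        clearance = 2.0
        # dense-sampling oracle over each screw segment
        def oracle():
            for screw in plate11.screws:
                o = t.apply(screw.origin)
                d = t.rotation @ screw.direction
                samples = o + np.outer(np.linspace(0, screw.length, 2000), d)
                dists = np.linalg.norm(
                    fossa[None, :, :] - samples[:, None, :], axis=2)
                if dists.min() < clearance - 1e-6:
                    return False
            return True
        checks = check_screws(plate11, matched_femur, t,
                              fossa_clearance=clearance)
        assert checks["fossa_clear"] == oracle()
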