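import numpy as np
import pytest

import spinereg as sr
from spinereg.contours import contour_from_silhouette
from spinereg.geometry import RigidTransform
from spinereg.projection import project_point, silhouette_contour
from spinereg.registration import (
    RegistrationError,
    RegistrationOptions,
    VertebraRegistration,
    initialize_pose,
    place_environment,
    register_spine,
)


@pytest.fixture(scope="module")
def mesh(nominal_shapes):
    return sr.make_vertebra(nominal_shapes[2])


@pytest.fixture(scope="module")
def gt_pose():
    return RigidTransform.from_axis_angle([1, 0, 0], 6.0, [3.0, -4.0, 8.0])


@pytest.fixture(scope="module")
def exact_targets(mesh, gt_pose, env):
    return {
        name: silhouette_contour(mesh, gt_pose, view, 0.5)
        for name, view in env.views.items()
    }


def pose_error(pose, truth):
    d = pose.invert() @ truth
    return d.rotation_angle_deg(), d.translation_norm()


class TestPlaceEnvironment:
    def test_zero_offsets_identity(self, env):
        moved = place_environment(env)
        assert np.allclose(moved.frontal.source, env.frontal.source)
        assert np.allclose(moved.sagittal.detector_origin, env.sagittal.detector_origin)

    def test_z_offset_shifts_projections_consistently(self, env):
        moved = place_environment(env, z_offset=50.0)
        p = np.array([10.0, -5.0, 30.0])
        for name in ("frontal", "sagittal"):
            v0, v1 = env.views[name], moved.views[name]
            uv0 = project_point(v0, p)
            # moving the whole environment up by 50 is equivalent to
            # moving the scene down by 50
            uv1 = project_point(v1, p + np.array([0.0, 0.0, 50.0]))
            assert np.allclose(uv0, uv1, atol=1e-9)

    def test_offsets_preserve_orthogonality(self, env):
        moved = place_environment(env, z_offset=80.0, in_plane_offsets=(12.0, -7.0))
        assert abs(moved.frontal.normal @ moved.sagittal.normal) < 1e-9


class TestInitializePose:
    def test_round_trip_from_exact_targets(self, mesh, gt_pose, exact_targets, env):
        init = initialize_pose(mesh, exact_targets, env)
        rot, trans = pose_error(init, gt_pose)
        assert rot < 5.0
        assert trans < 2.0

    def test_centroid_matching_recovers_large_translation(self, mesh, env):
        truth = RigidTransform(np.eye(3), [30.0, -15.0, 25.0])
        targets = {
            n: silhouette_contour(mesh, truth, v, 0.5) for n, v in env.views.items()
        }
        init = initialize_pose(mesh, targets, env)
        _, trans = pose_error(init, truth)
        assert trans < 2.0

    def test_degenerate_targets_rejected(self, mesh, env):
        from spinereg.contours import Contour2D

        line = Contour2D([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(RegistrationError, match="degenerate"):
            initialize_pose(mesh, {"frontal": line, "sagittal": line}, env)

    def test_near_isotropic_target_warns_of_ambiguity(self, env):
        import trimesh
        from spinereg.geometry import TriangleMesh

        s = trimesh.creation.icosphere(subdivisions=3, radius=15.0)
        ball = TriangleMesh(s.vertices, s.faces, "L1")
        targets = {
            n: silhouette_contour(ball, None, v, 0.5) for n, v in env.views.items()
        }
        with pytest.warns(RuntimeWarning, match="ambiguous"):
            initialize_pose(ball, targets, env)

    def test_missing_view_rejected(self, mesh, exact_targets, env):
        with pytest.raises(RegistrationError, match="sagittal"):
            initialize_pose(mesh, {"frontal": exact_targets["frontal"]}, env)


class TestRegisterVertebra:
    def test_exact_init_is_fixed_point(self, mesh, gt_pose, exact_targets, env):
        res = VertebraRegistration(mesh, exact_targets, env).fit(gt_pose)
        assert res.converged
        assert res.rms_residual < 0.5  # below the silhouette sampling step
        rot, trans = pose_error(res.final_pose, gt_pose)
        assert rot < 0.1 and trans < 0.1

    def test_recovery_from_perturbed_inits(self, mesh, gt_pose, exact_targets, env):
        rng = np.random.default_rng(1)
        rots, transs = [], []
        for _ in range(20):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            init = RigidTransform.from_axis_angle(axis, rng.uniform(-10, 10)) @ gt_pose
            init = RigidTransform(init.rotation, init.translation + rng.uniform(-10, 10, 3))
            res = VertebraRegistration(mesh, exact_targets, env).fit(init)
            rot, trans = pose_error(res.final_pose, gt_pose)
            rots.append(rot)
            transs.append(trans)
        assert np.median(rots) < 0.5
        assert np.median(transs) < 0.5

    def test_objective_monotone_over_iterations(self, mesh, gt_pose, exact_targets, env):
        init = RigidTransform.from_axis_angle([1, 0, 0], 8.0) @ gt_pose
        res = VertebraRegistration(mesh, exact_targets, env).fit(init)
        hist = np.array(res.history)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_large_misalignment_never_silent(self, mesh, gt_pose, exact_targets, env):
        init = RigidTransform.from_axis_angle([1, 0, 0], 45.0) @ gt_pose
        res = VertebraRegistration(mesh, exact_targets, env).fit(init)
        rot, trans = pose_error(res.final_pose, gt_pose)
        recovered = rot < 1.0 and trans < 1.0
        flagged = (not res.converged) or res.rms_residual > 1.0
        assert recovered or flagged

    def test_partial_corpus_like_contours(self, mesh, gt_pose, exact_targets, env):
        partial = {}
        for n, sil in exact_targets.items():
            N = len(sil.points)
            partial[n] = contour_from_silhouette(
                sil, [(0, int(0.25 * N)), (int(0.5 * N), int(0.65 * N))]
            )
        init = RigidTransform.from_axis_angle([1, 0, 0], 4.0, [2.0, 0.0, -2.0]) @ gt_pose
        res = VertebraRegistration(mesh, partial, env).fit(init)
        rot, trans = pose_error(res.final_pose, gt_pose)
        assert rot < 1.0 and trans < 1.0

    def test_translation_equivariance(self, mesh, gt_pose, env):
        # moving scene, targets and environment together leaves residuals
        # unchanged
        targets = {
            n: silhouette_contour(mesh, gt_pose, v, 0.5) for n, v in env.views.items()
        }
        init = RigidTransform.from_axis_angle([1, 0, 0], 3.0, [1.0, 1.0, 1.0]) @ gt_pose
        r0 = VertebraRegistration(mesh, targets, env).fit(init)

        shift = np.array([20.0, -10.0, 35.0])
        env2 = env.translated(shift)
        gt2 = RigidTransform(gt_pose.rotation, gt_pose.translation + shift)
        targets2 = {
            n: silhouette_contour(mesh, gt2, v, 0.5) for n, v in env2.views.items()
        }
        init2 = RigidTransform(init.rotation, init.translation + shift)
        r1 = VertebraRegistration(mesh, targets2, env2).fit(init2)
        assert r0.rms_residual == pytest.approx(r1.rms_residual, abs=1e-6)

    def test_out_of_reach_targets_error_names_view(self, mesh, gt_pose, exact_targets, env):
        far = RigidTransform(np.eye(3), [300.0, 0.0, 0.0]) @ gt_pose
        with pytest.raises(RegistrationError, match="frontal|sagittal"):
            VertebraRegistration(
                mesh, exact_targets, env, RegistrationOptions(correspondence_cap=5.0)
            ).fit(far)


class TestRegisterSpine:
    @pytest.fixture(scope="class")
    def pose_pair(self, nominal_shapes):
        supine = sr.SagittalPlan((2.0, 4.0, 8.0, 12.0, 14.0))
        standing = sr.SagittalPlan((3.1, 5.2, 9.4, 13.0, 15.5))
        return sr.make_pose_pair(nominal_shapes, supine, standing)

    def test_supine_to_standing_round_trip(self, pose_pair, env):
        supine, standing, gt = pose_pair
        targets = {
            v.label: {
                n: silhouette_contour(v.mesh, v.transform, view, 0.5)
                for n, view in env.views.items()
            }
            for v in standing
        }
        results = register_spine(supine, targets, env)
        assert results.all_converged
        for res, truth, sv in zip(results, gt, supine):
            # final_pose acts on the posed supine mesh; compare in the
            # same frame
            rot, trans = pose_error(res.final_pose @ sv.transform, truth @ sv.transform)
            assert rot < 1.0
            assert trans < 1.0

    def test_missing_vertebra_targets_named(self, pose_pair, env):
        supine, standing, _ = pose_pair
        targets = {
            v.label: {
                n: silhouette_contour(v.mesh, v.transform, view, 0.5)
                for n, view in env.views.items()
            }
            for v in standing
            if v.label != "L3"
        }
        with pytest.raises(RegistrationError, match="L3"):
            register_spine(supine, targets, env)

    def test_options_validation(self):
        with pytest.raises(ValueError):
            RegistrationOptions(max_iterations=0)
        with pytest.raises(ValueError):
            RegistrationOptions(view_weights=(0.0, 0.0))
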