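import numpy as np
import pytest
import shapely
import trimesh

from spinereg.geometry import RigidTransform, TriangleMesh
from spinereg.projection import (
    BiplanarEnvironment,
    ProjectionView,
    ProjectionError,
    default_environment,
    project_point,
    render_silhouette_radiograph,
    silhouette_contour,
)

SID, SOD = 1800.0, 1400.0


def sphere_mesh(radius=1.0, center=(0, 0, 0), subdivisions=3):
    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(s.vertices + np.asarray(center, float), s.faces, "L1")


class TestProjectPoint:
    def test_axial_point_maps_to_principal_point(self, env):
        uv = project_point(env.frontal, [0.0, 0.0, 0.0])
        assert np.allclose(uv, [0.0, 0.0], atol=1e-12)

    def test_magnification_is_sid_over_sod(self, env):
        # a point offset laterally in the plane at the source-object
        # distance magnifies by SID/SOD exactly (similar triangles)
        uv = project_point(env.frontal, [37.0, 0.0, 0.0])
        assert uv[0] == pytest.approx(37.0 * SID / SOD, rel=1e-12)
        uv = project_point(env.sagittal, [0.0, -12.0, 25.0])
        assert uv[0] == pytest.approx(-12.0 * SID / SOD, rel=1e-12)
        assert uv[1] == pytest.approx(25.0 * SID / SOD, rel=1e-12)

    def test_orthographic_offsets_are_unmagnified(self):
        env = default_environment(orthographic=True)
        uv = project_point(env.frontal, [37.0, 123.0, -4.0])
        assert np.allclose(uv, [37.0, -4.0], atol=1e-12)

    def test_ray_parallel_to_detector_raises(self, env):
        with pytest.raises(ProjectionError):
            # same y as the source: the ray never meets the detector plane
            project_point(env.frontal, [100.0, SOD, 0.0])

    def test_point_at_source_raises(self, env):
        with pytest.raises(ProjectionError):
            project_point(env.frontal, env.frontal.source)


class TestEnvironmentInvariants:
    def test_detectors_are_orthogonal(self, env):
        assert abs(env.frontal.normal @ env.sagittal.normal) < 1e-9

    def test_non_orthogonal_detectors_rejected(self, env):
        tilted = ProjectionView(
            "sagittal",
            source=(SOD, 0, 0),
            detector_origin=(SOD - SID, 0, 0),
            u=(0.0, np.cos(0.1), np.sin(0.1)),
            v=(0.0, -np.sin(0.1), np.cos(0.1)),
        )
        # axes remain orthonormal but the plane normal now tilts off x
        with pytest.raises(ValueError):
            BiplanarEnvironment(env.frontal, _rotate_about_v(tilted))

    def test_sid_exceeds_sod(self):
        with pytest.raises(ValueError):
            default_environment(sid=1000.0, sod=1400.0)

    def test_axes_must_be_orthonormal(self):
        with pytest.raises(ValueError):
            ProjectionView(
                "frontal",
                source=(0, SOD, 0),
                detector_origin=(0, SOD - SID, 0),
                u=(1.0, 0.0, 0.0),
                v=(0.5, 0.0, 1.0),
            )

    def test_translation_preserves_orthogonality(self, env):
        moved = env.translated([10.0, -5.0, 40.0])
        assert abs(moved.frontal.normal @ moved.sagittal.normal) < 1e-9


def _rotate_about_v(view):
    a = np.deg2rad(5.0)
    R = np.array(
        [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1.0]]
    )
    return ProjectionView(
        view.name, R @ view.source, R @ view.detector_origin, R @ view.u, view.v
    )


class TestSilhouette:
    def test_sphere_orthographic_circle(self):
        env = default_environment(orthographic=True)
        c = silhouette_contour(sphere_mesh(), None, env.frontal, resolution=0.2)
        area = shapely.Polygon(c.points).area
        assert area == pytest.approx(np.pi, rel=0.02)

    def test_sphere_perspective_radius_closed_form(self, env):
        # tangency cone: detector radius = SID * r / sqrt(d^2 - r^2)
        r, d = 20.0, SOD
        c = silhouette_contour(sphere_mesh(r), None, env.frontal, resolution=0.2)
        expected = SID * r / np.sqrt(d * d - r * r)
        area = shapely.Polygon(c.points).area
        assert area == pytest.approx(np.pi * expected**2, rel=0.02)
        radii = np.linalg.norm(c.points, axis=1)
        assert radii.mean() == pytest.approx(expected, rel=0.02)

    def test_box_orthographic_cross_section(self):
        env = default_environment(orthographic=True)
        b = trimesh.creation.box((30.0, 20.0, 14.0))
        mesh = TriangleMesh(b.vertices, b.faces, "L2")
        c = silhouette_contour(mesh, None, env.frontal, resolution=0.5)
        minx, miny, maxx, maxy = shapely.Polygon(c.points).bounds
        assert (maxx - minx) == pytest.approx(30.0, abs=0.5)
        assert (maxy - miny) == pytest.approx(14.0, abs=0.5)

    def test_planar_lamina_area_scales_as_magnification_squared(self, env):
        # flat square at the object plane: footprint area x (SID/SOD)^2
        sq = TriangleMesh(
            [[-10, 0, -10], [10, 0, -10], [10, 0, 10], [-10, 0, 10]],
            [[0, 1, 2], [0, 2, 3]],
            "L1",
        )
        c = silhouette_contour(sq, None, env.frontal, resolution=0.2)
        area = shapely.Polygon(c.points).area
        assert area == pytest.approx(400.0 * (SID / SOD) ** 2, rel=0.01)

    def test_boundary_vertices_densified_to_resolution(self, env, nominal_vertebra):
        c = silhouette_contour(
            nominal_vertebra, RigidTransform.identity(), env.sagittal, resolution=0.4
        )
        pts = np.vstack([c.points, c.points[:1]])
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert steps.max() <= 0.4 + 1e-9

    def test_pose_moves_silhouette(self, env):
        # an object at the source-object plane shifted laterally moves its
        # silhouette by the magnified amount
        mesh = sphere_mesh(12.0)
        t = RigidTransform(np.eye(3), [15.0, 0.0, 0.0])
        c0 = silhouette_contour(mesh, None, env.frontal, 0.5)
        c1 = silhouette_contour(mesh, t, env.frontal, 0.5)
        shift = c1.points.mean(axis=0) - c0.points.mean(axis=0)
        assert shift[0] == pytest.approx(15.0 * SID / SOD, rel=0.01)


class TestRenderRadiograph:
    def test_empty_scene_is_uniform_background(self, env):
        img = render_silhouette_radiograph([], env.frontal)
        assert np.all(img.pixels == 0.0)

    def test_noiseless_unblurred_render_is_binary(self, env, straight_spine):
        img = render_silhouette_radiograph(
            straight_spine, env.frontal, noise_sd=0.0, blur_sigma_px=0.0
        )
        assert set(np.unique(img.pixels)) <= {0.0, 1.0}
        assert img.pixels.sum() > 0

    def test_seeded_render_is_deterministic(self, env, straight_spine):
        a = render_silhouette_radiograph(straight_spine, env.frontal, 0.05, seed=7)
        b = render_silhouette_radiograph(straight_spine, env.frontal, 0.05, seed=7)
        assert np.array_equal(a.pixels, b.pixels)

    def test_mm_pixel_round_trip(self, env):
        img = render_silhouette_radiograph([], env.frontal)
        uv = np.array([[12.3, -45.6], [0.0, 0.0]])
        back = img.rowcol_to_mm(img.mm_to_rowcol(uv))
        assert np.allclose(back, uv, atol=1e-9)
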