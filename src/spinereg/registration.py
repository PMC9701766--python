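"""Contour-based rigid 2D-3D registration of vertebrae to biplanar views.

The procedure mirrors a four-step clinical workflow: (1) place the
calibrated biplanar environment once per case, (2) coarse per-vertebra
initialisation from silhouette/target centroids and principal axes,
(3) target contour selection (see :mod:`spinereg.contours`), and
(4) automatic refinement.  Refinement alternates correspondence search
and a Gauss-Newton pose update: in each view the mesh's projected
silhouette outline is intersected with the densified target samples
(nearest-point pairs, capped at ``correspondence_cap``), each silhouette
point is anchored to the 3D mesh vertex that projects closest to it, and
the 6-DOF pose increment (axis-angle about the object centroid +
translation) minimising the squared point-to-tangent residuals over both
views is applied.  Steps that would increase the true pooled
point-to-silhouette cost are backtracked, so the objective is
non-increasing across accepted iterations.

Exposed in two shapes: ``VertebraRegistration(...).fit()`` returning a
:class:`RegistrationResult` (the modelling-object interface), and the thin
functional wrappers :func:`register_vertebra` / :func:`register_spine`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .contours import as_contour_object
from .geometry import LABELS, RigidTransform, SpineModel, TriangleMesh
from .projection import BiplanarEnvironment, ProjectionView, silhouette_contour

__all__ = [
    "RegistrationOptions",
    "RegistrationResult",
    "RegistrationError",
    "VertebraRegistration",
    "SpineRegistrationResults",
    "place_environment",
    "initialize_pose",
    "register_vertebra",
    "register_spine",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RegistrationOptions:
    """Tunables of the automatic refinement.

    ``convergence_tol`` is the change in pooled RMS residual (mm) below
    which iteration stops; ``correspondence_cap`` discards target samples
    farther than this from the projected silhouette; ``view_weights``
    weights the (frontal, sagittal) residuals; ``densify_step`` is the
    target-contour sampling step; ``resolution`` the silhouette boundary
    sampling step.
    """

    max_iterations: int = 60
    convergence_tol: float = 0.01
    correspondence_cap: float = 10.0
    view_weights: tuple[float, float] = (1.0, 1.0)
    densify_step: float = 1.5
    resolution: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if min(self.convergence_tol, self.correspondence_cap, self.densify_step, self.resolution) <= 0:
            raise ValueError("tolerances and steps must be positive")
        w = self.view_weights
        if len(w) != 2 or min(w) < 0 or max(w) == 0:
            raise ValueError("view_weights must be non-negative, not both zero")


@dataclass
class RegistrationResult:
    """Outcome of one vertebra's refinement.

    ``final_pose`` maps the input mesh frame to the world (standing)
    frame.  ``rms_residual`` pools the matched target-to-silhouette
    distances over both views, in detector millimetres.
    """

    final_pose: RigidTransform
    rms_residual: float
    iterations: int
    converged: bool
    per_view_residuals: dict[str, float]
    n_correspondences: dict[str, int]
    label: str | None = None
    history: list[float] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Registration result{f' [{self.label}]' if self.label else ''}",
            f"  converged        : {self.converged}",
            f"  iterations       : {self.iterations}",
            f"  rms residual     : {self.rms_residual:.4f} mm",
        ]
        for v, r in self.per_view_residuals.items():
            lines.append(
                f"  {v:<8} residual : {r:.4f} mm  ({self.n_correspondences[v]} pairs)"
            )
        return "\n".join(lines)


def place_environment(
    env: BiplanarEnvironment,
    z_offset: float = 0.0,
    in_plane_offsets: tuple[float, float] = (0.0, 0.0),
) -> BiplanarEnvironment:
    """Rigidly translate the whole biplanar environment (sources and
    detectors together) — the once-per-case adjustment that puts all
    registrations of a case into one shared coordinate system.  Offsets
    are (patient-left, anterior) in-plane plus a cranio-caudal z shift.
    """
    dx, dy = in_plane_offsets
    return env.translated(np.array([dx, dy, z_offset], dtype=float))


# ---------------------------------------------------------------------------

def _principal_angle(points: np.ndarray) -> tuple[float, float]:
    """Orientation (deg, in (-90, 90]) of the dominant 2D principal axis
    and the eigenvalue ratio (ambiguity indicator)."""
    c = points - points.mean(axis=0)
    cov = c.T @ c / len(c)
    w, V = np.linalg.eigh(cov)
    ang = np.rad2deg(np.arctan2(V[1, -1], V[0, -1]))
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    ratio = w[0] / w[1] if w[1] > 0 else 1.0
    return float(ang), float(ratio)


def _wrap_half(angle: float) -> float:
    """Wrap to (-90, 90] (principal axes are sign-ambiguous)."""
    a = (angle + 90.0) % 180.0 - 90.0
    return 90.0 if a == -90.0 else a


def initialize_pose(
    mesh: TriangleMesh,
    targets: dict,
    env: BiplanarEnvironment,
    resolution: float = 1.0,
    densify_step: float = 2.0,
) -> RigidTransform:
    """Coarse pose from biplanar centroid and principal-axis matching.

    Stands in for the manual per-vertebra alignment step: translation is
    chosen (least squares over both views' ray constraints) so the
    projected silhouette centroid lands on the target centroid, and an
    in-plane rotation about each view's principal axis aligns the 2D
    second-moment axes.  Returns a world-frame transform to pre-multiply
    onto the mesh's current pose.  Warns when the target's principal axes
    are nearly degenerate (orientation ambiguous).
    """
    views = env.views
    tgt_samples = {}
    for name, view in views.items():
        if name not in targets:
            raise RegistrationError(f"no target contour for view {name!r}")
        obj = as_contour_object(targets[name])
        pts = obj.densified(densify_step)
        if len(pts) < 3 or np.linalg.matrix_rank(pts - pts.mean(axis=0), tol=1e-8) < 2:
            raise RegistrationError(f"degenerate target contour in view {name!r}")
        tgt_samples[name] = pts

    pose = RigidTransform.identity()
    pose = _match_centroids(mesh, pose, tgt_samples, views, resolution, densify_step)

    # in-plane rotations, one per view, composed about the object centroid
    center = pose.apply(mesh.centroid)
    rot = RigidTransform.identity()
    for name, view in views.items():
        sil = silhouette_contour(mesh, pose, view, resolution)
        a_sil, _ = _principal_angle(sil.densified(densify_step))
        a_tgt, ratio = _principal_angle(tgt_samples[name])
        if abs(1.0 - ratio) < 0.05:
            warnings.warn(
                f"view {name!r}: target principal axes nearly degenerate "
                "(eigenvalues within 5%); in-plane orientation is ambiguous",
                RuntimeWarning,
                stacklevel=2,
            )
        delta = _wrap_half(a_tgt - a_sil)
        axis = view.normal
        # rotating the object by +delta about the view normal rotates its
        # projection by +delta in (u, v)
        rot = RigidTransform.rotation_about(axis, delta, center) @ rot
    pose = rot @ pose
    pose = _match_centroids(mesh, pose, tgt_samples, views, resolution, densify_step)
    return pose


def _match_centroids(mesh, pose, tgt_samples, views, resolution, densify_step, iters=3):
    for _ in range(iters):
        rows, rhs = [], []
        center = pose.apply(mesh.centroid)
        for name, view in views.items():
            sil = silhouette_contour(mesh, pose, view, resolution)
            c_sil = sil.densified(densify_step).mean(axis=0)
            c_tgt = tgt_samples[name].mean(axis=0)
            J = _projection_point_jacobian(view, center)
            rows.append(J)
            rhs.append(c_tgt - c_sil)
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        dt, *_ = np.linalg.lstsq(A, b, rcond=None)
        pose = RigidTransform(np.eye(3), dt) @ pose
        if np.linalg.norm(dt) < 1e-3:
            break
    return pose


def _projection_point_jacobian(view: ProjectionView, p: np.ndarray, eps: float = 1.0):
    """d(uv)/d(xyz) of the point projection, by central differences."""
    J = np.empty((2, 3))
    for k in range(3):
        dp = np.zeros(3)
        dp[k] = eps
        J[:, k] = (view.project_points(p + dp) - view.project_points(p - dp)) / (2 * eps)
    return J


# ---------------------------------------------------------------------------

class VertebraRegistration:
    """Model object: one vertebra mesh vs its biplanar target contours.

    Parameters
    ----------
    mesh:
        The vertebra surface in its native frame (poses returned by
        :meth:`fit` map this frame to world coordinates).
    targets:
        Mapping ``view name -> Contour2D | ContourObject | list`` of
        target contour sections, in detector mm.
    env:
        The calibrated biplanar environment.
    options:
        :class:`RegistrationOptions`; defaults are sensible for
        sub-millimetre synthetic work.
    """

    def __init__(
        self,
        mesh: TriangleMesh,
        targets: dict,
        env: BiplanarEnvironment,
        options: RegistrationOptions | None = None,
    ):
        self.mesh = mesh
        self.env = env
        self.options = options or RegistrationOptions()
        self.targets = {}
        self._tgt_samples = {}
        for name in env.views:
            if name not in targets:
                raise RegistrationError(f"no target contour for view {name!r}")
            obj = as_contour_object(targets[name])
            self.targets[name] = obj
            self._tgt_samples[name] = obj.densified(self.options.densify_step)
        self._weights = dict(zip(env.views, self.options.view_weights))

    # -- pieces ------------------------------------------------------------
    def initialize(self) -> RigidTransform:
        return initialize_pose(
            self.mesh,
            self.targets,
            self.env,
            resolution=max(self.options.resolution, 1.0),
            densify_step=self.options.densify_step,
        )

    def _silhouette(self, pose, view):
        return silhouette_contour(self.mesh, pose, view, self.options.resolution)

    def _correspondences(self, pose: RigidTransform):
        """Per view: matched (target sample, silhouette point, outward
        tangent-normal, anchor 3D vertex) sets plus distances."""
        opts = self.options
        out = {}
        verts_world = pose.apply(self.mesh.vertices)
        for name, view in self.env.views.items():
            sil = self._silhouette(pose, view)
            ring = sil.geometry
            q = self._tgt_samples[name]
            pts = shapely.points(q)
            s_arc = shapely.line_locate_point(ring, pts)
            s_pts = shapely.get_coordinates(shapely.line_interpolate_point(ring, s_arc))
            d = np.linalg.norm(q - s_pts, axis=1)
            keep = d <= opts.correspondence_cap
            if not keep.any():
                raise RegistrationError(
                    f"view {name!r}: no correspondences within "
                    f"{opts.correspondence_cap} mm"
                )
            q_k, s_k, arc_k = q[keep], s_pts[keep], s_arc[keep]
            # boundary normal from the local tangent of the ring
            eps = opts.resolution / 2.0
            t0 = shapely.get_coordinates(
                shapely.line_interpolate_point(ring, (arc_k - eps) % ring.length)
            )
            t1 = shapely.get_coordinates(
                shapely.line_interpolate_point(ring, (arc_k + eps) % ring.length)
            )
            tang = t1 - t0
            nrm = np.linalg.norm(tang, axis=1)
            nrm[nrm == 0] = 1.0
            tang /= nrm[:, None]
            normal = np.column_stack([-tang[:, 1], tang[:, 0]])
            # anchor each silhouette point to the mesh vertex projecting
            # nearest to it
            proj = view.project_points(verts_world)
            tree = cKDTree(proj)
            _, vidx = tree.query(s_k)
            out[name] = {
                "q": q_k,
                "s": s_k,
                "normal": normal,
                "vidx": vidx,
                "d": d[keep],
                "view": view,
            }
        return out

    def _pooled_rms(self, corr) -> float:
        num = sum(self._weights[n] * (c["d"] ** 2).sum() for n, c in corr.items())
        den = sum(self._weights[n] * len(c["d"]) for n, c in corr.items())
        return float(np.sqrt(num / den))

    def _per_view_rms(self, corr) -> dict[str, float]:
        return {
            n: float(np.sqrt((c["d"] ** 2).mean())) for n, c in corr.items()
        }

    def _step(self, pose: RigidTransform, corr) -> RigidTransform:
        """One damped Gauss-Newton increment (axis-angle about the current
        object centroid + translation) on point-to-tangent residuals."""
        center = pose.apply(self.mesh.centroid)
        blocks = []
        for name, c in corr.items():
            X = pose.apply(self.mesh.vertices[c["vidx"]])
            blocks.append(
                (c["view"], X, c["q"], c["normal"], np.sqrt(self._weights[name]))
            )

        def residuals(p):
            rot = RigidTransform.from_rotvec(p[:3])
            res = []
            for view, X, q, normal, w in blocks:
                Y = rot.apply(X - center) + center + p[3:]
                proj = view.project_points(Y)
                res.append(w * np.einsum("ij,ij->i", proj - q, normal))
            return np.concatenate(res)

        sol = least_squares(residuals, np.zeros(6), method="lm", max_nfev=40)
        rot = RigidTransform.from_rotvec(sol.x[:3])
        delta = RigidTransform(
            rot.rotation, center + sol.x[3:] - rot.rotation @ center
        )
        return delta

    # -- main loop ---------------------------------------------------------
    def fit(self, init: RigidTransform | None = None) -> RegistrationResult:
        """Run the automatic refinement from ``init`` (default: the
        coarse biplanar initialisation)."""
        opts = self.options
        pose = init if init is not None else self.initialize()
        corr = self._correspondences(pose)
        rms = self._pooled_rms(corr)
        if not np.isfinite(rms):
            raise RegistrationError("non-finite registration cost")
        history = [rms]
        converged = False
        iterations = 0
        for iterations in range(1, opts.max_iterations + 1):
            delta = self._step(pose, corr)
            accepted = False
            for _ in range(5):  # backtracking keeps the cost non-increasing
                cand = delta @ pose
                cand_corr = self._correspondences(cand)
                cand_rms = self._pooled_rms(cand_corr)
                if cand_rms <= rms + 1e-12:
                    accepted = True
                    break
                delta = _half_step(delta)
            if not accepted:
                converged = True
                break
            change = rms - cand_rms
            pose, corr, rms = cand, cand_corr, cand_rms
            history.append(rms)
            if not np.isfinite(rms):
                raise RegistrationError("non-finite registration cost")
            if change < opts.convergence_tol:
                converged = True
                break
        return RegistrationResult(
            final_pose=pose,
            rms_residual=rms,
            iterations=iterations,
            converged=converged,
            per_view_residuals=self._per_view_rms(corr),
            n_correspondences={n: len(c["d"]) for n, c in corr.items()},
            label=self.mesh.label,
            history=history,
        )


def _half_step(delta: RigidTransform) -> RigidTransform:
    """Halve a pose increment (axis-angle and translation)."""
    ang = delta.rotation_angle_deg()
    if ang < 1e-12:
        R = np.eye(3)
    else:
        # extract the rotation axis from the skew-symmetric part
        A = delta.rotation - delta.rotation.T
        axis = np.array([A[2, 1], A[0, 2], A[1, 0]])
        n = np.linalg.norm(axis)
        axis = axis / n if n > 0 else np.array([1.0, 0.0, 0.0])
        R = RigidTransform.from_axis_angle(axis, ang / 2.0).rotation
    return RigidTransform(R, delta.translation / 2.0)


def register_vertebra(
    mesh: TriangleMesh,
    init: RigidTransform,
    targets: dict,
    env: BiplanarEnvironment,
    options: RegistrationOptions | None = None,
) -> RegistrationResult:
    """Functional wrapper around :class:`VertebraRegistration`."""
    return VertebraRegistration(mesh, targets, env, options).fit(init)


class SpineRegistrationResults:
    """Per-vertebra results of a whole-spine registration, L1..S."""

    def __init__(self, results, supine: SpineModel):
        self.results = list(results)
        self.supine = supine

    def __iter__(self):
        return iter(self.results)

    def __getitem__(self, label: str) -> RegistrationResult:
        for r in self.results:
            if r.label == label:
                return r
        raise KeyError(label)

    @property
    def all_converged(self) -> bool:
        return all(r.converged for r in self.results)

    def registered_model(self) -> SpineModel:
        """Standing model: supine poses composed with the fitted
        world-frame corrections."""
        return self.supine.with_transforms([r.final_pose for r in self.results])

    def summary(self) -> str:
        lines = ["Spine registration (L1..S)"]
        for r in self.results:
            lines.append(
                f"  {r.label:<3} rms={r.rms_residual:7.4f} mm  "
                f"iters={r.iterations:3d}  converged={r.converged}"
            )
        return "\n".join(lines)


def register_spine(
    spine_supine: SpineModel,
    targets: dict,
    env: BiplanarEnvironment,
    options: RegistrationOptions | None = None,
    inits: dict | None = None,
) -> SpineRegistrationResults:
    """Register every vertebra of a supine model independently.

    ``targets`` maps vertebra label -> view name -> contour(s); ``inits``
    optionally maps labels to initial world-frame corrections (default:
    the coarse biplanar initialisation per vertebra).  Errors are
    re-raised with the offending vertebra named.
    """
    for label in LABELS:
        if label not in targets:
            raise RegistrationError(f"missing target contours for vertebra {label}")
    results = []
    for vert in spine_supine:
        label = vert.label
        try:
            model = VertebraRegistration(
                vert.posed_mesh(), targets[label], env, options
            )
            init = inits.get(label) if inits else None
            results.append(model.fit(init))
        except (RegistrationError, ValueError) as exc:
            raise RegistrationError(f"vertebra {label}: {exc}") from exc
    return SpineRegistrationResults(results, spine_supine)
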