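"""Parametric synthetic lumbar spines with known ground-truth alignment.

The generator builds simplified vertebrae — a wedge-able rounded block for
the vertebral body plus box/cylinder posterior elements (pedicles,
transverse and spinous processes) — and stacks them with prescribed
sagittal intersegmental angles and disc gaps.  Every pose is known exactly,
so the whole registration/measurement pipeline can be validated without
patient data.

Conventions (see :mod:`spinereg.geometry`): +z cranial, +y anterior,
+x patient-left; sagittal rotations are about the x axis; lordotic
(extension) angles are positive.  An intersegmental angle is defined
between the caudal endplate of the upper vertebra and the cranial endplate
of the lower one, so with wedged vertebrae the lumbar lordosis (cranial L1
endplate vs cranial S1 endplate) equals the sum of the five intersegmental
angles plus the body wedges of L1..L5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh

from .geometry import LABELS, RigidTransform, SpineModel, TriangleMesh, VertebraPose

__all__ = [
    "VertebraShapeParams",
    "SagittalPlan",
    "make_vertebra",
    "assemble_spine",
    "make_pose_pair",
    "default_shape_set",
    "random_shape_set",
    "random_plan",
]


@dataclass(frozen=True)
class VertebraShapeParams:
    """Dimensions of one synthetic vertebra, millimetres / degrees."""

    body_width: float = 42.0  # left-right extent of the body
    body_depth: float = 30.0  # anterior-posterior extent of the body
    body_height: float = 26.0  # cranio-caudal extent of the body
    wedge_angle: float = 0.0  # cranial-vs-caudal endplate dihedral, degrees
    pedicle_length: float = 12.0
    transverse_process_length: float = 18.0
    spinous_process_length: float = 22.0
    seed: int = 0  # drives a small symmetric body-profile modulation
    label: str | None = None

    def __post_init__(self):
        for name in (
            "body_width",
            "body_depth",
            "body_height",
            "pedicle_length",
            "transverse_process_length",
            "spinous_process_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.wedge_angle) >= 30.0:
            raise ValueError("wedge_angle must satisfy |w| < 30 degrees")


@dataclass(frozen=True)
class SagittalPlan:
    """Per-segment sagittal angles (L1-L2 ... L5-S1) and disc gaps.

    ``lordosis`` is the plan's own lumbar lordosis for wedge-free
    vertebrae; the assembled model's ground truth additionally includes the
    body wedges (see :func:`assemble_spine`).
    """

    intersegmental_angles: tuple[float, ...] = (2.0, 4.0, 8.0, 12.0, 14.0)
    disc_heights: tuple[float, ...] = (10.0, 10.0, 11.0, 11.0, 12.0)

    def __post_init__(self):
        object.__setattr__(
            self, "intersegmental_angles", tuple(float(a) for a in self.intersegmental_angles)
        )
        object.__setattr__(
            self, "disc_heights", tuple(float(h) for h in self.disc_heights)
        )
        if len(self.intersegmental_angles) != 5 or len(self.disc_heights) != 5:
            raise ValueError("plan needs 5 intersegmental angles and 5 disc heights")
        if any(h <= 0 for h in self.disc_heights):
            raise ValueError("disc heights must be positive")
        if any(abs(a) >= 45 for a in self.intersegmental_angles):
            raise ValueError("intersegmental angles must satisfy |a| < 45 degrees")

    @property
    def lordosis(self) -> float:
        return float(sum(self.intersegmental_angles))


_SUBDIV = 4.0  # mm target edge length; sets silhouette/endplate sampling density


def _subdivided_box(extents, max_edge=_SUBDIV) -> trimesh.Trimesh:
    b = trimesh.creation.box(extents)
    v, f = trimesh.remesh.subdivide_to_size(b.vertices, b.faces, max_edge)
    return trimesh.Trimesh(v, f, process=False)


def _rounded_rect_ring(hx: float, hy: float, chamfer: float = 0.18, n_arc: int = 3):
    """Planar ring approximating a rounded rectangle with half-extents
    (hx, hy); mirror-symmetric in both axes."""
    r = chamfer * min(hx, hy)
    cx, cy = hx - r, hy - r
    # build one quadrant and mirror it for exact symmetry
    quad = []
    for a in np.linspace(0.0, 90.0, n_arc + 1):
        t = np.deg2rad(a)
        quad.append((cx + r * np.cos(t), cy + r * np.sin(t)))
    quad = np.asarray(quad)
    ring = np.vstack(
        [
            quad,
            quad[::-1] * np.array([-1.0, 1.0]),
            quad * np.array([-1.0, -1.0]),
            quad[::-1] * np.array([1.0, -1.0]),
        ]
    )
    # drop duplicated seam points
    keep = np.ones(len(ring), dtype=bool)
    keep[1:] = np.linalg.norm(np.diff(ring, axis=0), axis=1) > 1e-12
    return ring[keep]


def make_vertebra(params: VertebraShapeParams) -> TriangleMesh:
    """Build one synthetic vertebra in its local frame.

    Local frame: origin at the body centre, +z cranial, +y anterior,
    +x left.  The mesh is a union of closed primitives (body, two
    pedicles, two transverse processes, spinous process); it is
    mirror-symmetric about x = 0, and its cranial/caudal endplates are
    planar with a dihedral equal to ``wedge_angle``.  Deterministic for a
    given parameter set.
    """
    W, D, H = params.body_width, params.body_depth, params.body_height
    rng = np.random.default_rng(params.seed)
    bulge = rng.uniform(0.01, 0.04)  # fractional mid-body barrel bulge

    # vertebral body: convex hull of two tilted endplate rings (rounded
    # rectangles) and a bulged mid ring.  Convex by construction (so the
    # silhouette machinery can take the exact hull path), endplates exactly
    # planar with dihedral = wedge_angle, mirror-symmetric about x = 0.
    ring = _rounded_rect_ring(W / 2.0, D / 2.0)
    shear = np.tan(np.deg2rad(params.wedge_angle) / 2.0)
    top = np.column_stack(
        [ring[:, 0], ring[:, 1], H / 2.0 + shear * ring[:, 1]]
    )
    bottom = np.column_stack(
        [ring[:, 0], ring[:, 1], -H / 2.0 - shear * ring[:, 1]]
    )
    mid = np.column_stack(
        [(1 + bulge) * ring[:, 0], (1 + bulge) * ring[:, 1], np.zeros(len(ring))]
    )
    hull = trimesh.convex.convex_hull(np.vstack([top, mid, bottom]))
    v, f = trimesh.remesh.subdivide_to_size(hull.vertices, hull.faces, _SUBDIV)
    body = trimesh.Trimesh(v, f, process=False)

    parts = [body]

    # pedicles: small boxes just posterior to the body wall
    ped_x = W / 3.0
    ped = np.array([7.0, params.pedicle_length + 0.3, 9.0])
    for sx in (-1.0, 1.0):
        p = _subdivided_box(ped)
        p.apply_translation(
            (sx * ped_x, -D / 2.0 - params.pedicle_length / 2.0 + 0.15, 0.0)
        )
        parts.append(p)

    # transverse processes: lateral cylinders slightly overlapping the pedicles
    tl = params.transverse_process_length
    for sx in (-1.0, 1.0):
        c = trimesh.creation.cylinder(radius=3.0, height=tl, sections=16)
        cv, cf = trimesh.remesh.subdivide_to_size(c.vertices, c.faces, _SUBDIV)
        c = trimesh.Trimesh(cv, cf, process=False)
        c.apply_transform(
            trimesh.transformations.rotation_matrix(np.pi / 2.0, [0, 1, 0])
        )
        c.apply_translation(
            (sx * (ped_x + 2.5 + tl / 2.0), -D / 2.0 - params.pedicle_length / 2.0, 0.0)
        )
        parts.append(c)

    # midline lamina bridge: connects body and spinous process across the
    # sagittal midplane so the midsagittal cut of a vertebra is a single
    # connected region
    bridge = _subdivided_box((6.0, params.pedicle_length + 4.0, 6.0))
    bridge.apply_translation((0.0, -D / 2.0 - params.pedicle_length / 2.0 + 1.5, 0.0))
    parts.append(bridge)

    # spinous process: box sloping caudally, starting behind the pedicles
    sl = params.spinous_process_length
    sp = _subdivided_box((7.0, sl, 9.0))
    slope = np.deg2rad(40.0)
    sp.apply_transform(trimesh.transformations.rotation_matrix(slope, [1, 0, 0]))
    y0 = -D / 2.0 - params.pedicle_length
    sp.apply_translation(
        (0.0, y0 - np.cos(slope) * sl / 2.0 + 0.5, -np.sin(slope) * sl / 2.0)
    )
    parts.append(sp)

    combined = trimesh.util.concatenate(parts)
    return TriangleMesh(combined.vertices, combined.faces, label=params.label)


def _endplate_tilts(shapes) -> tuple[np.ndarray, np.ndarray]:
    """Cranial and caudal endplate tilt of each vertebra relative to its
    own transverse plane (half-wedge each side)."""
    w = np.array([s.wedge_angle for s in shapes])
    return w / 2.0, -w / 2.0


def assemble_spine(shapes, plan: SagittalPlan) -> SpineModel:
    """Stack six vertebrae (L1..L5, S) according to a sagittal plan.

    Vertebrae are chained caudal to cranial: each vertebra is rotated
    about the x (left-right) axis so that the angle between adjacent
    endplates equals the planned intersegmental angle, and translated so
    the endplate centres are separated by the planned disc height.  The
    assembled model is centred on the origin, and carries the implied
    ground-truth angles in ``planned_angles`` (a plain dict; the
    measurement module's AngleSet mirrors it).

    Raises ``ValueError`` if adjacent vertebral bodies would interpenetrate.
    """
    shapes = list(shapes)
    if len(shapes) != 6:
        raise ValueError("need 6 shape parameter sets (L1..L5, S)")
    shapes = [
        replace(s, label=lbl) if s.label != lbl else s
        for s, lbl in zip(shapes, LABELS)
    ]
    meshes = [make_vertebra(s) for s in shapes]
    return _assemble(meshes, shapes, plan)


def _assemble(meshes, shapes, plan: SagittalPlan) -> SpineModel:
    w_cr, w_ca = _endplate_tilts(shapes)  # degrees
    theta = np.asarray(plan.intersegmental_angles)  # L1-L2 .. L5-S1
    # ground-truth lordosis includes the lumbar body wedges (L1..L5)
    ll_true = float(theta.sum() + np.array([s.wedge_angle for s in shapes[:5]]).sum())

    # vertebra tilts, caudal to cranial; index 5 = sacrum
    tilt = np.zeros(6)
    tilt[5] = -ll_true / 2.0 - w_cr[5]  # balance the arc around vertical
    for i in range(4, -1, -1):  # L5 ... L1
        tilt[i] = tilt[i + 1] + theta[i] + (w_cr[i + 1] - w_ca[i])

    # interpenetration guard: facing endplates diverge by the segment angle
    for i in range(5):
        half_depth = max(shapes[i].body_depth, shapes[i + 1].body_depth) / 2.0
        gap = plan.disc_heights[i] - np.tan(np.deg2rad(abs(theta[i]))) * half_depth
        if gap <= 0.1:
            raise ValueError(
                f"segment {LABELS[i]}-{LABELS[i + 1]}: planned angle "
                f"{theta[i]:.1f} deg interpenetrates at disc height "
                f"{plan.disc_heights[i]:.1f} mm"
            )

    x = np.array([1.0, 0.0, 0.0])
    poses: list[RigidTransform] = [None] * 6
    poses[5] = RigidTransform.from_axis_angle(x, tilt[5])
    for i in range(4, -1, -1):
        low, up = i + 1, i
        R_low, R_up = poses[low].rotation, RigidTransform.from_axis_angle(x, tilt[up]).rotation
        # world cranial-endplate centre/normal of the lower vertebra
        h_low = shapes[low].body_height
        c_low = poses[low].apply(np.array([0.0, 0.0, h_low / 2.0]))
        n_low = R_low @ _tilted_up(w_cr[low])
        disc_c = c_low + 0.5 * plan.disc_heights[i] * n_low
        # place the upper vertebra so its caudal endplate centre sits the
        # other half-disc above the disc centre, along its own caudal normal
        h_up = shapes[up].body_height
        n_up = R_up @ _tilted_up(w_ca[up])  # upward normal of the caudal plate
        c_up_target = disc_c + 0.5 * plan.disc_heights[i] * n_up
        t_up = c_up_target - R_up @ np.array([0.0, 0.0, -h_up / 2.0])
        poses[up] = RigidTransform(R_up, t_up, _skip_check=True)

    model = SpineModel(
        [VertebraPose(m, p) for m, p in zip(meshes, poses)],
        planned_angles={
            "intersegmental": tuple(float(a) for a in theta),
            "LL": ll_true,
        },
    )
    # centre the whole model on the origin
    center = np.mean([v.posed_mesh().centroid for v in model], axis=0)
    shift = RigidTransform(np.eye(3), -center)
    return model.with_transforms([shift] * 6)


def _tilted_up(tilt_deg: float) -> np.ndarray:
    """Unit 'up' normal of an endplate tilted by ``tilt_deg`` about x."""
    a = np.deg2rad(tilt_deg)
    return np.array([0.0, -np.sin(a), np.cos(a)])


def make_pose_pair(shapes, supine_plan: SagittalPlan, standing_plan: SagittalPlan):
    """Build supine and standing models from identical meshes.

    Returns ``(supine, standing, transforms)`` where ``transforms[k]``
    maps vertebra ``k``'s supine pose exactly onto its standing pose
    (world frame, pre-multiplied).
    """
    shapes = [
        replace(s, label=lbl) if s.label != lbl else s
        for s, lbl in zip(shapes, LABELS)
    ]
    meshes = [make_vertebra(s) for s in shapes]
    supine = _assemble(meshes, shapes, supine_plan)
    standing = _assemble(meshes, shapes, standing_plan)
    gt = [
        sv.transform @ su.transform.invert()
        for su, sv in zip(supine, standing)
    ]
    return supine, standing, gt


# ---------------------------------------------------------------------------
# Stock parameter sets used by the validation experiments

#: Typical lumbar fractions of total lordosis, L1-L2 .. L5-S1 (caudal
#: segments contribute the most, as in normal standing alignment).
SEGMENT_FRACTIONS = (0.08, 0.13, 0.19, 0.26, 0.34)


def default_shape_set(seed: int = 0) -> list[VertebraShapeParams]:
    """Six nominal shape parameter sets, L1..L5 growing slightly caudally
    and a wider, wedged sacral block."""
    shapes = []
    for i, lbl in enumerate(LABELS[:5]):
        shapes.append(
            VertebraShapeParams(
                body_width=40.0 + 1.5 * i,
                body_depth=29.0 + 1.0 * i,
                body_height=26.0,
                wedge_angle=0.0,
                seed=seed * 7 + i,
                label=lbl,
            )
        )
    shapes.append(
        VertebraShapeParams(
            body_width=58.0,
            body_depth=32.0,
            body_height=34.0,
            wedge_angle=12.0,
            transverse_process_length=24.0,
            spinous_process_length=14.0,
            seed=seed * 7 + 5,
            label="S",
        )
    )
    return shapes


def random_shape_set(rng: np.random.Generator) -> list[VertebraShapeParams]:
    """Per-case anatomical variation: +/-8% sizes, small lumbar wedges."""
    base = default_shape_set(seed=int(rng.integers(0, 2**31 - 1)))
    out = []
    for s in base:
        f = rng.uniform(0.92, 1.08)
        wedge = s.wedge_angle + rng.uniform(-3.0, 3.0)
        out.append(
            replace(
                s,
                body_width=s.body_width * f,
                body_depth=s.body_depth * rng.uniform(0.95, 1.05),
                body_height=s.body_height * rng.uniform(0.95, 1.05),
                wedge_angle=float(wedge),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return out


def random_plan(
    rng: np.random.Generator,
    lordosis: float,
    jitter_deg: float = 1.5,
) -> SagittalPlan:
    """Plan with the given total lordosis split physiologically across the
    five segments, plus per-segment jitter (which preserves the total only
    in expectation)."""
    angles = np.array(SEGMENT_FRACTIONS) * lordosis
    angles = angles + rng.uniform(-jitter_deg, jitter_deg, size=5)
    discs = rng.uniform(9.5, 12.5, size=5)
    return SagittalPlan(tuple(angles), tuple(discs))
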