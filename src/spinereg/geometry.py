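"""Rigid-body transforms and labelled triangle meshes.

World frame convention (used by every module): right-handed, millimetres,
+z cranial, +y anterior, +x patient-left.  Angles at API boundaries are in
degrees; radians appear only inside numerical kernels.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
import trimesh

__all__ = [
    "LABELS",
    "RigidTransform",
    "TriangleMesh",
    "VertebraPose",
    "SpineModel",
]

#: Anatomical ordering, cranial to caudal.  "S" is the sacrum (S1 endplate).
LABELS = ("L1", "L2", "L3", "L4", "L5", "S")

_ORTHO_TOL = 1e-9


class RigidTransform:
    """An element of SE(3): ``x -> R @ x + t`` with R special orthogonal.

    Rotations are stored as 3x3 matrices and re-projected onto SO(3) by SVD
    whenever they are built from arbitrary input, so repeated composition
    during iterative optimisation cannot drift away from the group.
    """

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation=None, translation=None, *, _skip_check=False):
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {R.shape}")
        if t.shape != (3,):
            raise ValueError(f"translation must be a 3-vector, got {t.shape}")
        if not _skip_check:
            err = np.abs(R.T @ R - np.eye(3)).max()
            if err > 1e-6 or abs(np.linalg.det(R) - 1.0) > 1e-6:
                raise ValueError("rotation is not special orthogonal")
            if err > _ORTHO_TOL:
                R = _project_so3(R)
        self.rotation = R
        self.rotation.setflags(write=False)
        self.translation = t
        self.translation.setflags(write=False)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def from_axis_angle(axis, angle_deg: float, translation=None) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` (through the origin)."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("axis must be nonzero")
        return RigidTransform(
            _rotvec_to_matrix(axis / n * np.deg2rad(angle_deg)),
            translation,
            _skip_check=True,
        )

    @staticmethod
    def from_rotvec(rotvec, translation=None) -> "RigidTransform":
        """Axis-angle 3-vector in radians (the optimiser's parameterisation)."""
        return RigidTransform(
            _rotvec_to_matrix(np.asarray(rotvec, dtype=float)),
            translation,
            _skip_check=True,
        )

    @staticmethod
    def rotation_about(axis, angle_deg: float, center) -> "RigidTransform":
        """Rotation about an axis through an arbitrary point ``center``."""
        c = np.asarray(center, dtype=float)
        r = RigidTransform.from_axis_angle(axis, angle_deg)
        return RigidTransform(r.rotation, c - r.rotation @ c, _skip_check=True)

    # -- algebra -----------------------------------------------------------
    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        R = self.rotation @ other.rotation
        return RigidTransform(
            _project_so3(R),
            self.rotation @ other.translation + self.translation,
            _skip_check=True,
        )

    __matmul__ = compose

    def invert(self) -> "RigidTransform":
        Rt = self.rotation.T.copy()
        return RigidTransform(Rt, -Rt @ self.translation, _skip_check=True)

    def apply(self, points) -> np.ndarray:
        """Transform an (n, 3) array (or a single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    # -- diagnostics -------------------------------------------------------
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))

    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    def is_close(self, other: "RigidTransform", rot_tol=1e-9, trans_tol=1e-9) -> bool:
        """Entry-wise comparison (rotation matrix and translation)."""
        return (
            np.abs(self.rotation - other.rotation).max() <= rot_tol
            and np.abs(self.translation - other.translation).max() <= trans_tol
        )

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
        }

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(
            np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            np.asarray(d["translation"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @staticmethod
    def from_json(s: str) -> "RigidTransform":
        return RigidTransform.from_dict(json.loads(s))

    def __repr__(self):
        return (
            f"RigidTransform(angle={self.rotation_angle_deg():.3f} deg, "
            f"t={np.array2string(self.translation, precision=2)})"
        )


def _project_so3(R: np.ndarray) -> np.ndarray:
    """Nearest special-orthogonal matrix (Frobenius norm), via SVD."""
    U, _, Vt = np.linalg.svd(R)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
    return U @ D @ Vt


def _rotvec_to_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues formula; safe at the origin."""
    theta = np.linalg.norm(rotvec)
    if theta < 1e-12:
        K = _skew(rotvec)
        return np.eye(3) + K + 0.5 * K @ K
    k = rotvec / theta
    K = _skew(k)
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def _skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float)


_MIN_FACE_AREA = 1e-9  # mm^2; degenerate faces below this are dropped


class TriangleMesh:
    """A labelled triangle surface mesh in millimetres.

    Thin immutable wrapper over vertex/face arrays with a cached
    :mod:`trimesh` view for surface queries.  Degenerate faces (area below
    1e-9 mm^2) are removed on construction.
    """

    def __init__(self, vertices, faces, label: str | None = None):
        v = np.ascontiguousarray(vertices, dtype=float)
        f = np.ascontiguousarray(faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        areas = _triangle_areas(v[f]) if len(f) else np.empty(0)
        keep = areas >= _MIN_FACE_AREA
        if not keep.all():
            f = f[keep]
            areas = areas[keep]
        if len(f) == 0 or areas.sum() <= 0:
            raise ValueError("mesh has no non-degenerate faces")
        self.vertices = v
        self.faces = f
        self.label = label
        self.vertices.setflags(write=False)
        self.faces.setflags(write=False)
        self._trimesh = None
        self._components = None

    # -- derived quantities ------------------------------------------------
    @property
    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    @property
    def face_areas(self) -> np.ndarray:
        return _triangle_areas(self.triangles)

    @property
    def area(self) -> float:
        return float(self.face_areas.sum())

    @property
    def centroid(self) -> np.ndarray:
        """Area-weighted surface centroid."""
        c = self.triangles.mean(axis=1)
        w = self.face_areas
        return (c * w[:, None]).sum(axis=0) / w.sum()

    @property
    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def as_trimesh(self) -> trimesh.Trimesh:
        if self._trimesh is None:
            self._trimesh = trimesh.Trimesh(
                vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
            )
        return self._trimesh

    @property
    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.as_trimesh().vertex_normals)

    @property
    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)

    @property
    def volume(self) -> float:
        """Sum of component volumes (overlap between closed components,
        if any, is counted once per component)."""
        return float(sum(abs(c.volume) for c in self.closed_components()))

    def closed_components(self) -> list[trimesh.Trimesh]:
        """Connected components as trimesh objects, cached."""
        if self._components is None:
            tm = self.as_trimesh()
            self._components = tm.split(only_watertight=False)
            if len(self._components) == 0:
                self._components = [tm]
        return list(self._components)

    # -- operations --------------------------------------------------------
    def transformed(self, t: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(t.apply(self.vertices), self.faces, self.label)

    def __repr__(self):
        return (
            f"TriangleMesh(label={self.label!r}, nv={len(self.vertices)}, "
            f"nf={len(self.faces)})"
        )


def _triangle_areas(tri: np.ndarray) -> np.ndarray:
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def apply(t: RigidTransform, m: TriangleMesh) -> TriangleMesh:
    """Functional alias: rigidly move a mesh."""
    return m.transformed(t)


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Apply ``b`` first, then ``a``."""
    return a.compose(b)


def invert(t: RigidTransform) -> RigidTransform:
    return t.invert()


class VertebraPose:
    """A vertebra mesh in its native (CT) frame plus its world pose."""

    __slots__ = ("mesh", "transform", "_posed")

    def __init__(self, mesh: TriangleMesh, transform: RigidTransform | None = None):
        self.mesh = mesh
        self.transform = transform or RigidTransform.identity()
        self._posed = None

    @property
    def label(self) -> str | None:
        return self.mesh.label

    def posed_mesh(self) -> TriangleMesh:
        """Mesh in world coordinates (cached)."""
        if self._posed is None:
            self._posed = self.mesh.transformed(self.transform)
        return self._posed

    def with_transform(self, t: RigidTransform) -> "VertebraPose":
        return VertebraPose(self.mesh, t)

    def __repr__(self):
        return f"VertebraPose({self.label}, {self.transform})"


class SpineModel:
    """Ordered lumbar spine: L1..L5 and the sacrum, each with a pose.

    The optional ``planned_angles`` attribute carries the ground-truth
    sagittal plan when the model was produced by the synthetic generator.
    """

    def __init__(self, vertebrae: Sequence[VertebraPose], planned_angles=None):
        labels = tuple(v.label for v in vertebrae)
        if labels != LABELS:
            raise ValueError(f"expected labels {LABELS} in order, got {labels}")
        self.vertebrae = list(vertebrae)
        self.planned_angles = planned_angles

    def __iter__(self) -> Iterable[VertebraPose]:
        return iter(self.vertebrae)

    def __len__(self):
        return len(self.vertebrae)

    def __getitem__(self, label: str) -> VertebraPose:
        for v in self.vertebrae:
            if v.label == label:
                return v
        raise KeyError(label)

    @property
    def labels(self):
        return LABELS

    def posed_meshes(self) -> list[TriangleMesh]:
        return [v.posed_mesh() for v in self.vertebrae]

    def with_transforms(self, transforms: Sequence[RigidTransform]) -> "SpineModel":
        """New model with each vertebra's pose pre-multiplied by a transform."""
        if len(transforms) != len(self.vertebrae):
            raise ValueError("need one transform per vertebra")
        return SpineModel(
            [
                VertebraPose(v.mesh, t @ v.transform)
                for v, t in zip(self.vertebrae, transforms)
            ],
            planned_angles=self.planned_angles,
        )

    def is_valid_standing(self) -> bool:
        """Centroids strictly ordered cranial (L1) to caudal (S) along +z."""
        z = [v.posed_mesh().centroid[2] for v in self.vertebrae]
        return all(z[i] > z[i + 1] for i in range(len(z) - 1))

    def __repr__(self):
        return f"SpineModel({len(self.vertebrae)} elements)"
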