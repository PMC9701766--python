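"""Simulated biplanar radiographic environment.

Two calibrated views (frontal and sagittal) with point radiation sources
and planar detectors, mutually orthogonal as in a standing biplanar
acquisition.  Provides central (perspective) projection of 3D points, the
exact projected silhouette outline of a mesh, and rendering of synthetic
silhouette radiographs.

Detector coordinates are millimetres with the origin at the principal
point (detector centre): u runs patient-left in the frontal view and
patient-anterior in the sagittal view, v runs cranial.  Image rasters put
row 0 at the most cranial row (v decreasing with row index); this y-down
raster vs v-up geometry conversion lives only in :class:`RadiographImage`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy import ndimage
from scipy.spatial import ConvexHull

from .contours import Contour2D
from .geometry import RigidTransform, SpineModel, TriangleMesh

__all__ = [
    "ProjectionView",
    "BiplanarEnvironment",
    "RadiographImage",
    "default_environment",
    "project_point",
    "silhouette_contour",
    "render_silhouette_radiograph",
]


class ProjectionError(ValueError):
    pass


@dataclass(frozen=True)
class ProjectionView:
    """One calibrated projection view.

    ``source`` is the focal spot; the detector plane passes through
    ``detector_origin`` (the principal point) and is spanned by the
    orthonormal axes ``u`` and ``v``.  ``orthographic=True`` switches to
    parallel projection along the principal axis (source at infinity),
    which is handy for analytic checks.
    """

    name: str
    source: np.ndarray
    detector_origin: np.ndarray
    u: np.ndarray
    v: np.ndarray
    pixel_spacing: float = 0.5
    size: tuple[int, int] = (840, 1040)  # (u px, v px)
    orthographic: bool = False

    def __post_init__(self):
        for f in ("source", "detector_origin", "u", "v"):
            object.__setattr__(self, f, np.asarray(getattr(self, f), dtype=float))
        un, vn = np.linalg.norm(self.u), np.linalg.norm(self.v)
        if abs(un - 1) > 1e-9 or abs(vn - 1) > 1e-9 or abs(self.u @ self.v) > 1e-9:
            raise ValueError("detector axes must be orthonormal")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if abs(self.normal @ (self.source - self.detector_origin)) < 1e-9:
            raise ValueError("source must not lie on the detector plane")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(self.u, self.v)

    @property
    def principal_axis(self) -> np.ndarray:
        """Unit vector from the source toward the detector."""
        d = self.detector_origin - self.source
        return d / np.linalg.norm(d)

    @property
    def sid(self) -> float:
        """Source-to-image (detector) distance, mm."""
        return float(np.linalg.norm(self.detector_origin - self.source))

    def project_points(self, points) -> np.ndarray:
        """Project (n, 3) world points onto the detector, returning (n, 2)
        coordinates in detector millimetres."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        n = self.normal
        if self.orthographic:
            d = self.principal_axis
            denom = n @ d
            t = ((self.detector_origin - p) @ n) / denom
            X = p + t[:, None] * d
        else:
            rays = p - self.source
            denom = rays @ n
            if np.any(np.abs(denom) < 1e-12):
                raise ProjectionError(
                    f"{self.name}: ray through point is parallel to the detector"
                )
            t = ((self.detector_origin - self.source) @ n) / denom
            X = self.source + t[:, None] * rays
        rel = X - self.detector_origin
        out = np.column_stack([rel @ self.u, rel @ self.v])
        return out[0] if np.asarray(points).ndim == 1 else out

    def translated(self, offset) -> "ProjectionView":
        off = np.asarray(offset, dtype=float)
        return ProjectionView(
            self.name,
            self.source + off,
            self.detector_origin + off,
            self.u,
            self.v,
            self.pixel_spacing,
            self.size,
            self.orthographic,
        )

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "source": list(self.source),
            "detector_origin": list(self.detector_origin),
            "u": list(self.u),
            "v": list(self.v),
            "pixel_spacing": self.pixel_spacing,
            "size": list(self.size),
            "orthographic": self.orthographic,
        }

    @staticmethod
    def from_dict(d: dict) -> "ProjectionView":
        return ProjectionView(
            d["name"],
            d["source"],
            d["detector_origin"],
            d["u"],
            d["v"],
            float(d.get("pixel_spacing", 0.5)),
            tuple(d.get("size", (840, 1040))),
            bool(d.get("orthographic", False)),
        )


@dataclass(frozen=True)
class BiplanarEnvironment:
    """Frontal + sagittal calibrated views with orthogonal detectors."""

    frontal: ProjectionView
    sagittal: ProjectionView

    def __post_init__(self):
        c = abs(self.frontal.normal @ self.sagittal.normal)
        if c > np.sin(np.deg2rad(0.1)):
            raise ValueError("detector planes must be mutually orthogonal")

    @property
    def views(self) -> dict[str, ProjectionView]:
        return {self.frontal.name: self.frontal, self.sagittal.name: self.sagittal}

    def translated(self, offset) -> "BiplanarEnvironment":
        return BiplanarEnvironment(
            self.frontal.translated(offset), self.sagittal.translated(offset)
        )

    def to_dict(self) -> dict:
        return {"frontal": self.frontal.to_dict(), "sagittal": self.sagittal.to_dict()}

    @staticmethod
    def from_dict(d: dict) -> "BiplanarEnvironment":
        return BiplanarEnvironment(
            ProjectionView.from_dict(d["frontal"]),
            ProjectionView.from_dict(d["sagittal"]),
        )


def default_environment(
    sid: float = 1800.0,
    sod: float = 1400.0,
    pixel_spacing: float = 0.5,
    size: tuple[int, int] = (840, 1040),
    orthographic: bool = False,
) -> BiplanarEnvironment:
    """Standard geometry: object at the origin, frontal beam along -y
    (source anterior), sagittal beam along -x (source patient-left);
    principal axes through the origin.  SID/SOD default to common standing
    radiography values since acquisition geometry is site configuration.
    """
    if not sid > sod > 0:
        raise ValueError("need SID > SOD > 0")
    frontal = ProjectionView(
        "frontal",
        source=(0.0, sod, 0.0),
        detector_origin=(0.0, sod - sid, 0.0),
        u=(1.0, 0.0, 0.0),  # patient-left
        v=(0.0, 0.0, 1.0),  # cranial
        pixel_spacing=pixel_spacing,
        size=size,
        orthographic=orthographic,
    )
    sagittal = ProjectionView(
        "sagittal",
        source=(sod, 0.0, 0.0),
        detector_origin=(sod - sid, 0.0, 0.0),
        u=(0.0, 1.0, 0.0),  # patient-anterior
        v=(0.0, 0.0, 1.0),
        pixel_spacing=pixel_spacing,
        size=size,
        orthographic=orthographic,
    )
    return BiplanarEnvironment(frontal, sagittal)


def project_point(view: ProjectionView, p) -> np.ndarray:
    """Central projection of a single world point, detector mm."""
    p = np.asarray(p, dtype=float)
    if not view.orthographic and np.linalg.norm(p - view.source) < 1e-9:
        raise ProjectionError("point coincides with the radiation source")
    return view.project_points(p)


# ---------------------------------------------------------------------------
# Silhouettes

def _component_partition(mesh: TriangleMesh):
    """Cached connected-component face partition with convexity flags.

    Convexity is decided once on the native-frame mesh (it is rigid
    invariant) so silhouettes of posed meshes can take the fast
    convex-hull path without re-splitting.
    """
    cached = getattr(mesh, "_silhouette_partition", None)
    if cached is not None:
        return cached
    import trimesh as _trimesh

    tm = mesh.as_trimesh()
    if len(tm.faces) == 0:
        raise ProjectionError("empty mesh")
    labels = _trimesh.graph.connected_component_labels(
        tm.face_adjacency, node_count=len(tm.faces)
    )
    parts = []
    for lab in np.unique(labels):
        fidx = np.where(labels == lab)[0]
        faces = mesh.faces[fidx]
        vidx = np.unique(faces)
        sub = _trimesh.Trimesh(
            mesh.vertices[vidx],
            np.searchsorted(vidx, faces),
            process=False,
        )
        parts.append({"vertex_idx": vidx, "faces": faces, "convex": bool(sub.is_convex)})
    mesh._silhouette_partition = parts
    return parts


def silhouette_polygon(
    mesh: TriangleMesh, pose: RigidTransform | None, view: ProjectionView
) -> shapely.Polygon:
    """Exact outer footprint of the posed mesh on the detector, as a
    shapely polygon in detector mm.

    Convex components contribute the convex hull of their projected
    vertices (the exact perspective silhouette of a convex solid); other
    components contribute the union of their projected triangles.
    """
    verts = mesh.vertices if pose is None else pose.apply(mesh.vertices)
    proj = view.project_points(verts)
    polys = []
    for part in _component_partition(mesh):
        pts = proj[part["vertex_idx"]]
        if part["convex"]:
            hull = ConvexHull(pts)
            polys.append(shapely.Polygon(pts[hull.vertices]))
        else:
            tris = proj[part["faces"]]
            polys.append(shapely.union_all(shapely.polygons(tris)))
    u = shapely.union_all(polys)
    u = shapely.make_valid(u)
    if u.is_empty:
        raise ProjectionError("mesh projects to an empty footprint")
    if isinstance(u, shapely.MultiPolygon):
        u = max(u.geoms, key=lambda g: g.area)
    elif not isinstance(u, shapely.Polygon):
        u = max(
            (g for g in getattr(u, "geoms", [u]) if isinstance(g, shapely.Polygon)),
            key=lambda g: g.area,
        )
    return u


def silhouette_contour(
    mesh: TriangleMesh,
    pose: RigidTransform | None,
    view: ProjectionView,
    resolution: float = 0.5,
) -> Contour2D:
    """Closed outer silhouette boundary of the posed mesh, densified so
    consecutive boundary vertices are at most ``resolution`` mm apart."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    poly = silhouette_polygon(mesh, pose, view)
    ring = shapely.segmentize(poly.exterior, resolution)
    pts = np.asarray(ring.coords)[:-1]  # drop duplicated closing vertex
    return Contour2D(pts, closed=True, label=mesh.label, view=view.name)


# ---------------------------------------------------------------------------
# Radiograph rendering

@dataclass
class RadiographImage:
    """A rendered (or loaded) radiograph: grayscale raster + geometry.

    ``pixels[0, 0]`` is the most cranial, smallest-u pixel; values are
    floats in [0, 1] for synthetic renders.
    """

    pixels: np.ndarray
    pixel_spacing: float
    view: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width u, height v) in mm."""
        nr, nc = self.pixels.shape
        return nc * self.pixel_spacing, nr * self.pixel_spacing

    def mm_to_rowcol(self, uv) -> np.ndarray:
        """Detector mm -> fractional (row, col) pixel coordinates."""
        uv = np.atleast_2d(np.asarray(uv, dtype=float))
        w, h = self.extent_mm
        col = (uv[:, 0] + w / 2.0) / self.pixel_spacing - 0.5
        row = (h / 2.0 - uv[:, 1]) / self.pixel_spacing - 0.5
        return np.column_stack([row, col])

    def rowcol_to_mm(self, rowcol) -> np.ndarray:
        rc = np.atleast_2d(np.asarray(rowcol, dtype=float))
        w, h = self.extent_mm
        u = (rc[:, 1] + 0.5) * self.pixel_spacing - w / 2.0
        v = h / 2.0 - (rc[:, 0] + 0.5) * self.pixel_spacing
        return np.column_stack([u, v])

    def contains_mm(self, uv) -> np.ndarray:
        rc = self.mm_to_rowcol(uv)
        nr, nc = self.pixels.shape
        return (
            (rc[:, 0] >= -0.5)
            & (rc[:, 0] <= nr - 0.5)
            & (rc[:, 1] >= -0.5)
            & (rc[:, 1] <= nc - 0.5)
        )


def render_silhouette_radiograph(
    spine,
    view: ProjectionView,
    noise_sd: float = 0.0,
    seed: int | None = None,
    blur_sigma_px: float = 1.0,
    foreground: float = 1.0,
) -> RadiographImage:
    """Binary-footprint radiograph of the scene (union of all meshes),
    optionally blurred and with additive Gaussian noise.

    ``spine`` may be a :class:`SpineModel` or any iterable of
    ``(mesh, pose)`` pairs; an empty iterable yields a uniform background.
    Deterministic for a given seed.
    """
    nu, nv = view.size
    img = np.zeros((nv, nu), dtype=float)
    ref = RadiographImage(img, view.pixel_spacing, view.name)

    if isinstance(spine, SpineModel):
        items = [(v.mesh, v.transform) for v in spine]
    else:
        items = list(spine)

    from skimage.draw import polygon as _sk_polygon

    for mesh, pose in items:
        poly = silhouette_polygon(mesh, pose, view)
        for geom in [poly]:
            rc = ref.mm_to_rowcol(np.asarray(geom.exterior.coords))
            rr, cc = _sk_polygon(rc[:, 0], rc[:, 1], shape=img.shape)
            img[rr, cc] = foreground
            for hole in geom.interiors:
                rc = ref.mm_to_rowcol(np.asarray(hole.coords))
                rr, cc = _sk_polygon(rc[:, 0], rc[:, 1], shape=img.shape)
                img[rr, cc] = 0.0

    if blur_sigma_px > 0 and items:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return RadiographImage(img, view.pixel_spacing, view.name)
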