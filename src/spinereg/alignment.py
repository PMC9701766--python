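"""Midsagittal sections and sagittal alignment angles.

Lumbar lordosis (LL) is measured between the cranial endplate of L1 and
the cranial endplate of S1; an intersegmental angle between the caudal
endplate of the upper and the cranial endplate of the lower vertebra of a
motion segment.  Lordotic (extension) angles are positive throughout.

Endplates are located by an explicit geometric rule (in place of a human
reading the image): candidate surface points are those whose outward
normal lies within 30 degrees of the vertebra's cranio-caudal axis and
whose height is within a 3 mm band of the extreme along that axis, and a
trimmed least-squares line/plane is fitted through them.  The same rule
drives the 3D-mesh path and the raster section-image path, so angles from
either agree closely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import ConvexHull
from skimage import measure as sk_measure
import trimesh

from .geometry import LABELS, SpineModel, TriangleMesh, VertebraPose

__all__ = [
    "AngleSet",
    "SectionImage",
    "midsagittal_plane",
    "section_image",
    "endplate_line",
    "compute_angles",
    "angle_abs_diff",
]

_NORMAL_CONE_DEG = 30.0  # endplate candidate normal cone half-angle
_HEIGHT_BAND_MM = 3.0  # height window isolating one endplate
_TRIM_RESIDUAL_MM = 0.8  # trimmed-fit outlier threshold


def _mode_band(s: np.ndarray, width: float = _HEIGHT_BAND_MM) -> np.ndarray:
    """Mask of the width-mm window along ``s`` holding the most points.

    The endplate is the dominant near-planar patch among the normal-cone
    candidates; picking the densest height window rejects small stray
    clusters (process tips, decoys) regardless of which side is extreme.
    """
    order = np.argsort(s)
    ss = s[order]
    hi = np.searchsorted(ss, ss + width, side="right")
    counts = hi - np.arange(len(ss))
    i = int(np.argmax(counts))
    lo_val = ss[i]
    return (s >= lo_val) & (s <= lo_val + width)


class MeasurementError(RuntimeError):
    pass


@dataclass(frozen=True)
class AngleSet:
    """Five intersegmental angles (L1-L2 .. L5-S1) plus LL, degrees."""

    intersegmental: tuple[float, float, float, float, float]
    LL: float

    def __post_init__(self):
        object.__setattr__(
            self, "intersegmental", tuple(float(a) for a in self.intersegmental)
        )
        object.__setattr__(self, "LL", float(self.LL))
        if len(self.intersegmental) != 5:
            raise ValueError("need 5 intersegmental angles")

    @staticmethod
    def from_plan(planned: dict) -> "AngleSet":
        """Ground-truth angles recorded by the synthetic generator."""
        return AngleSet(tuple(planned["intersegmental"]), planned["LL"])

    def as_dict(self) -> dict:
        d = {
            f"{LABELS[i]}{LABELS[i + 1]}": self.intersegmental[i] for i in range(5)
        }
        d["LL"] = self.LL
        return d

    def __iter__(self):
        return iter(self.intersegmental + (self.LL,))


def angle_abs_diff(a: AngleSet, b: AngleSet) -> AngleSet:
    """Element-wise absolute differences (degrees)."""
    return AngleSet(
        tuple(abs(x - y) for x, y in zip(a.intersegmental, b.intersegmental)),
        abs(a.LL - b.LL),
    )


# ---------------------------------------------------------------------------
# Midsagittal plane and section raster

def midsagittal_plane(spine: SpineModel) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal mid-plane between the extreme left and right vertex
    coordinates over the whole model.  Returns ``(origin, normal)``; the
    normal is the left-right (+x) axis."""
    if len(spine) == 0:
        raise MeasurementError("empty spine")
    xs = np.concatenate([v.posed_mesh().vertices[:, 0] for v in spine])
    mid = 0.5 * (xs.min() + xs.max())
    return np.array([mid, 0.0, 0.0]), np.array([1.0, 0.0, 0.0])


@dataclass
class SectionImage:
    """Filled raster of the mid-plane cut, with its mm geometry.

    ``pixels[0, 0]`` is the most cranial, most posterior pixel; column j
    maps to y (anterior) = ``y0 + (j + 0.5) * pixel_spacing`` and row i to
    z (cranial) = ``z0 - (i + 0.5) * pixel_spacing``.
    """

    pixels: np.ndarray
    pixel_spacing: float
    plane_origin: np.ndarray
    plane_normal: np.ndarray
    y0: float
    z0: float

    def __post_init__(self):
        n = np.asarray(self.plane_normal, dtype=float)
        n = n / np.linalg.norm(n)
        tilt = np.rad2deg(np.arccos(np.clip(abs(n[0]), -1, 1)))
        if tilt > 5.0:
            raise ValueError("section plane normal must be the left-right axis (within 5 deg)")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    def rowcol_to_yz(self, rowcol) -> np.ndarray:
        rc = np.atleast_2d(np.asarray(rowcol, dtype=float))
        y = self.y0 + (rc[:, 1] + 0.5) * self.pixel_spacing
        z = self.z0 - (rc[:, 0] + 0.5) * self.pixel_spacing
        return np.column_stack([y, z])

    @property
    def area_mm2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_spacing**2


def _cross_section_polygons(mesh: TriangleMesh, pose, plane_origin, plane_normal):
    """Shapely polygons of the posed mesh's cut by the plane, in (y, z)."""
    from .projection import _component_partition

    verts = mesh.vertices if pose is None else pose.apply(mesh.vertices)
    polys = []
    for part in _component_partition(mesh):
        vs = verts[part["vertex_idx"]]
        faces = np.searchsorted(part["vertex_idx"], part["faces"])
        segs = trimesh.intersections.mesh_plane(
            trimesh.Trimesh(vs, faces, process=False),
            plane_normal,
            plane_origin,
        )
        if len(segs) == 0:
            continue
        pts2 = segs[..., 1:]  # drop x: section lives in the (y, z) plane
        if part["convex"]:
            flat = pts2.reshape(-1, 2)
            if len(np.unique(flat.round(9), axis=0)) >= 3:
                try:
                    hull = ConvexHull(flat)
                    polys.append(shapely.Polygon(flat[hull.vertices]))
                    continue
                except Exception:
                    pass
        lines = shapely.union_all(shapely.linestrings(pts2))
        merged = shapely.polygonize([lines])
        for g in getattr(merged, "geoms", []):
            polys.append(g)
    return polys


def section_image(
    spine: SpineModel,
    plane: tuple[np.ndarray, np.ndarray] | None = None,
    pixel_spacing: float = 0.3,
) -> SectionImage:
    """Rasterise the filled mesh-plane cross-section of the whole model.

    The result is the synthetic analogue of a midsagittal section image:
    the same angle measurement applied to sagittal radiographs can be
    applied to it.
    """
    if plane is None:
        plane = midsagittal_plane(spine)
    origin, normal = np.asarray(plane[0], float), np.asarray(plane[1], float)
    polys = []
    for vert in spine:
        polys.extend(_cross_section_polygons(vert.mesh, vert.transform, origin, normal))
    if not polys:
        raise MeasurementError("plane does not intersect the model")
    union = shapely.make_valid(shapely.union_all(polys))
    miny, minz, maxy, maxz = union.bounds
    pad = 2.0 * pixel_spacing
    y0, z1 = miny - pad, maxz + pad
    ncols = int(np.ceil((maxy - miny + 2 * pad) / pixel_spacing))
    nrows = int(np.ceil((z1 - (minz - pad)) / pixel_spacing))
    jj, ii = np.meshgrid(np.arange(ncols), np.arange(nrows))
    yy = y0 + (jj + 0.5) * pixel_spacing
    zz = z1 - (ii + 0.5) * pixel_spacing
    inside = shapely.contains_xy(union, yy.ravel(), zz.ravel()).reshape(nrows, ncols)
    return SectionImage(
        pixels=inside.astype(np.uint8),
        pixel_spacing=pixel_spacing,
        plane_origin=origin,
        plane_normal=normal,
        y0=y0,
        z0=z1,
    )


# ---------------------------------------------------------------------------
# Endplate lines

def _trimmed_line_fit(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares 2D line with iterative outlier trimming.

    Returns (point on line, unit direction with positive y component).
    """
    pts = np.asarray(pts, dtype=float)
    for _ in range(3):
        c = pts.mean(axis=0)
        d = pts - c
        _, _, Vt = np.linalg.svd(d, full_matrices=False)
        direction = Vt[0]
        resid = np.abs(d @ np.array([-direction[1], direction[0]]))
        keep = resid <= max(_TRIM_RESIDUAL_MM, np.median(resid) * 3 + 1e-9)
        if keep.all() or keep.sum() < 6:
            break
        pts = pts[keep]
    c = pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts - c, full_matrices=False)
    direction = Vt[0]
    if direction[0] < 0:
        direction = -direction
    return c, direction


def _line_angle_deg(direction: np.ndarray) -> float:
    """Sagittal elevation of a (y, z) line direction: positive when the
    anterior end points cranially."""
    return float(np.rad2deg(np.arctan2(direction[1], direction[0])))


def _mesh_endplate_points(vert: VertebraPose, which: str) -> np.ndarray:
    """World-frame endplate candidate points of one vertebra (3D path)."""
    mesh = vert.posed_mesh()
    up = vert.transform.rotation @ np.array([0.0, 0.0, 1.0])
    sign = 1.0 if which == "cranial" else -1.0
    normals = mesh.vertex_normals
    cos_cone = np.cos(np.deg2rad(_NORMAL_CONE_DEG))
    cand = (normals @ (sign * up)) >= cos_cone
    if cand.sum() < 6:
        raise MeasurementError(
            f"{vert.label}: too few {which} endplate candidate points"
        )
    pts = mesh.vertices[cand]
    s = pts @ (sign * up)
    pts = pts[_mode_band(s)]
    if len(pts) < 6:
        raise MeasurementError(
            f"{vert.label}: too few {which} endplate points in the height band"
        )
    return pts


def _endplate_line_from_mesh(vert: VertebraPose, which: str, basis=None):
    """Fit the endplate line in a sagittal 2D basis.

    ``basis`` is a pair of 3D unit vectors (anterior-like, cranial-like)
    spanning the measurement plane; default is the world (y, z) plane.
    """
    pts3 = _mesh_endplate_points(vert, which)
    if basis is None:
        pts2 = pts3[:, 1:]
    else:
        e_a, e_c = basis
        pts2 = np.column_stack([pts3 @ e_a, pts3 @ e_c])
    return _trimmed_line_fit(pts2)


def _intrinsic_sagittal_basis(spine: SpineModel):
    """Anterior/cranial measurement axes from the mean vertebra
    orientation.  Using the model's own frame makes angle differences
    exactly invariant under whole-body rigid motion."""
    from .geometry import _project_so3

    Rbar = _project_so3(np.mean([v.transform.rotation for v in spine], axis=0))
    return Rbar @ np.array([0.0, 1.0, 0.0]), Rbar @ np.array([0.0, 0.0, 1.0])


def _section_components(section: SectionImage) -> list[dict]:
    """Labelled connected components of the section, cranial to caudal,
    each with sub-pixel boundary points and outward boundary normals."""
    from scipy import ndimage as _ndi

    lab = sk_measure.label(section.pixels > 0)
    comps = []
    for region in sk_measure.regionprops(lab):
        mask = (lab == region.label).astype(float)
        # smooth before tracing: marching squares on a raw binary mask
        # yields a staircase boundary whose local normals are unusable
        smooth = _ndi.gaussian_filter(np.pad(mask, 3, mode="constant"), 1.2)
        contours = sk_measure.find_contours(smooth, 0.5)
        boundary = max(contours, key=len) - 3.0  # undo padding
        yz = section.rowcol_to_yz(boundary)
        # outward normal: find_contours on padded masks traces with the
        # high side on the left; orient by signed area instead
        d = np.gradient(yz, axis=0)
        nrm = np.linalg.norm(d, axis=1)
        nrm[nrm == 0] = 1.0
        t = d / nrm[:, None]
        normal = np.column_stack([t[:, 1], -t[:, 0]])
        # orient outward: for a counter-clockwise loop in (y, z) the
        # left-hand perpendicular of the tangent points inward
        a, b = yz[:-1] - yz[0], yz[1:] - yz[0]
        area2 = (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]).sum()
        if area2 < 0:
            normal = -normal
        comps.append(
            {"centroid_z": float(yz[:, 1].mean()), "boundary": yz, "normal": normal}
        )
    comps.sort(key=lambda c: -c["centroid_z"])  # cranial first
    return comps


def _dominant_line(pts: np.ndarray, normals: np.ndarray):
    """Largest near-collinear subset of boundary points sharing a common
    normal direction (deterministic consensus search: every point's local
    tangent line is scored by its inlier count).

    The vertebral endplate is the longest straight boundary run among the
    candidates, so it wins against shorter box edges of the posterior
    elements.
    """
    n = len(pts)
    # inlier test: within 0.7 mm of the line and normal within 15 deg
    perp = normals  # local boundary normal == line normal candidate
    diff = pts[None, :, :] - pts[:, None, :]
    dist = np.abs(np.einsum("ijk,ik->ij", diff, perp))
    align = np.abs(normals @ perp.T) >= np.cos(np.deg2rad(15.0))
    inliers = (dist <= 0.7) & align
    counts = inliers.sum(axis=1)
    best = int(np.argmax(counts))
    if counts[best] < 6:
        raise MeasurementError("endplate support too small")
    # support the fit with every candidate near the winning line, whatever
    # its local normal: raster quantisation expresses a shallow slope as
    # flat runs joined by short steps, and the step points must be kept
    # for the average slope to be unbiased
    support = pts[dist[best] <= 0.7]
    # drop the run's extremities: mask smoothing rounds the plate corners,
    # which would otherwise bias the slope
    c = support.mean(axis=0)
    _, _, Vt = np.linalg.svd(support - c, full_matrices=False)
    s = (support - c) @ Vt[0]
    margin = 1.5
    core = (s > s.min() + margin) & (s < s.max() - margin)
    if core.sum() >= 6:
        support = support[core]
    return _trimmed_line_fit(support)


def _endplate_line_from_section(section: SectionImage, label: str, which: str):
    comps = _section_components(section)
    if len(comps) != 6:
        raise MeasurementError(
            f"expected 6 section components (L1..S), found {len(comps)}"
        )
    comp = comps[LABELS.index(label)]
    sign = 1.0 if which == "cranial" else -1.0
    up = np.array([0.0, sign * 1.0])
    # wide cone: tilted standing vertebrae can carry their endplates up to
    # ~35 deg from the horizontal; the consensus search below rejects the
    # extra non-endplate candidates this lets in
    cand = (comp["normal"] @ up) >= np.cos(np.deg2rad(40.0))
    if cand.sum() < 6:
        raise MeasurementError(f"{label}: {which} endplate not found in section")
    try:
        return _dominant_line(comp["boundary"][cand], comp["normal"][cand])
    except MeasurementError:
        raise MeasurementError(f"{label}: {which} endplate not found in section")


def endplate_line(obj, label: str, which: str):
    """Fit the requested endplate line in the sagittal plane.

    ``obj`` is either a :class:`SpineModel` / :class:`VertebraPose` (3D
    mesh path) or a :class:`SectionImage` (raster path).  Returns
    ``(point, direction, angle_deg)`` where the angle is measured against
    the world transverse plane, positive anterior-up.
    """
    if which not in ("cranial", "caudal"):
        raise ValueError("which must be 'cranial' or 'caudal'")
    if isinstance(obj, SectionImage):
        c, d = _endplate_line_from_section(obj, label, which)
    elif isinstance(obj, SpineModel):
        c, d = _endplate_line_from_mesh(obj[label], which)
    elif isinstance(obj, VertebraPose):
        c, d = _endplate_line_from_mesh(obj, which)
    else:
        raise TypeError("obj must be SpineModel, VertebraPose or SectionImage")
    return c, d, _line_angle_deg(d)


# ---------------------------------------------------------------------------

def compute_angles(obj) -> AngleSet:
    """Intersegmental angles and LL of a model or section image.

    Intersegmental angle i = (caudal endplate angle of the upper
    vertebra) - (cranial endplate angle of the lower vertebra);
    LL = (cranial L1) - (cranial S1); lordotic positive.
    """
    basis = _intrinsic_sagittal_basis(obj) if isinstance(obj, SpineModel) else None

    def _angle(lbl, which):
        if basis is not None:
            _, d = _endplate_line_from_mesh(obj[lbl], which, basis)
            return _line_angle_deg(d)
        return endplate_line(obj, lbl, which)[2]

    psi_cr, psi_ca = {}, {}
    errors = []
    for lbl in LABELS:
        try:
            psi_cr[lbl] = _angle(lbl, "cranial")
            if lbl != "S":
                psi_ca[lbl] = _angle(lbl, "caudal")
        except MeasurementError as exc:
            errors.append(str(exc))
    if errors:
        raise MeasurementError("; ".join(errors))
    inter = tuple(
        psi_ca[LABELS[i]] - psi_cr[LABELS[i + 1]] for i in range(5)
    )
    return AngleSet(inter, psi_cr["L1"] - psi_cr["S"])
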