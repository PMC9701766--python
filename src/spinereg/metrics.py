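"""Agreement and accuracy metrics.

* Dice similarity index ``DSI = 2|X & Y| / (|X| + |Y|)`` on voxel
  occupancy masks (meshes are voxelised at 0.6 mm by default, matching a
  typical CT reconstruction grid).
* Mean surface distance ``E_m(S1, S2) = (1/|S1|) \\int_{S1} e(p, S2) ds``
  — the area-weighted one-sided mean of exact point-to-surface distances,
  estimated by stratified per-triangle sampling; a symmetrised variant
  and the max (Hausdorff) distance are provided alongside.
* Two-way mixed-effects, absolute-agreement intraclass correlation
  (single-measurement ICC(A,1) and mean-of-k ICC(A,k)) with F-based 95%
  confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from scipy.spatial import ConvexHull, cKDTree
import trimesh

from .geometry import LABELS, RigidTransform, TriangleMesh

__all__ = [
    "VoxelMask",
    "voxelize",
    "voxelize_pair",
    "dice",
    "mean_surface_distance",
    "hausdorff_max",
    "point_surface_distances",
    "icc",
    "ICCResult",
    "AgreementReport",
    "build_agreement_report",
]

DEFAULT_VOXEL_MM = 0.6  # isotropic CT reconstruction grid


@dataclass
class VoxelMask:
    """Boolean occupancy on an axis-aligned isotropic grid."""

    occupancy: np.ndarray
    voxel_size: float
    origin: np.ndarray

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be 3D")

    @property
    def count(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        return self.count * self.voxel_size**3

    def same_grid(self, other: "VoxelMask") -> bool:
        return (
            abs(self.voxel_size - other.voxel_size) < 1e-12
            and self.occupancy.shape == other.occupancy.shape
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )


def _grid_from_bounds(bounds, voxel_size, margin=1):
    lo = np.floor(bounds[0] / voxel_size).astype(int) - margin
    hi = np.ceil(bounds[1] / voxel_size).astype(int) + margin
    origin = lo * voxel_size
    shape = tuple((hi - lo).astype(int))
    return origin, shape


def voxelize(
    mesh: TriangleMesh,
    pose: RigidTransform | None = None,
    voxel_size: float = DEFAULT_VOXEL_MM,
    origin=None,
    shape=None,
) -> VoxelMask:
    """Occupancy of voxels whose centres fall inside the posed mesh.

    The mesh must consist of closed (watertight) components; occupancy is
    the union over components.  The default grid is aligned to integer
    multiples of the voxel size, so translating the mesh and the origin
    together reproduces the identical occupancy pattern.
    """
    from .projection import _component_partition

    parts = _component_partition(mesh)
    verts = mesh.vertices if pose is None else pose.apply(mesh.vertices)
    for part in parts:
        sub = trimesh.Trimesh(
            verts[part["vertex_idx"]],
            np.searchsorted(part["vertex_idx"], part["faces"]),
            process=False,
        )
        if not sub.is_watertight:
            raise ValueError("mesh component is not watertight")
    bounds = np.vstack([verts.min(axis=0), verts.max(axis=0)])
    if origin is None or shape is None:
        origin, shape = _grid_from_bounds(bounds, voxel_size)
    origin = np.asarray(origin, dtype=float)

    nx, ny, nz = shape
    occ = np.zeros(shape, dtype=bool)
    xs = origin[0] + (np.arange(nx) + 0.5) * voxel_size
    ys = origin[1] + (np.arange(ny) + 0.5) * voxel_size
    zs = origin[2] + (np.arange(nz) + 0.5) * voxel_size
    xg, yg = np.meshgrid(xs, ys, indexing="ij")

    # slice the closed components plane-by-plane along z and fill the
    # union of cross-section polygons (robust to overlapping components)
    comps = []
    for part in parts:
        vs = verts[part["vertex_idx"]]
        faces = np.searchsorted(part["vertex_idx"], part["faces"])
        comps.append(
            (trimesh.Trimesh(vs, faces, process=False), part["convex"],
             vs[:, 2].min(), vs[:, 2].max())
        )
    for k, z in enumerate(zs):
        polys = []
        for tm, convex, zmin, zmax in comps:
            if z < zmin or z > zmax:
                continue
            segs = trimesh.intersections.mesh_plane(
                tm, np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, z])
            )
            if len(segs) == 0:
                continue
            pts2 = segs[..., :2]
            if convex:
                flat = pts2.reshape(-1, 2)
                if len(np.unique(flat.round(9), axis=0)) >= 3:
                    try:
                        hull = ConvexHull(flat)
                        polys.append(shapely.Polygon(flat[hull.vertices]))
                        continue
                    except Exception:
                        pass
            lines = shapely.union_all(shapely.linestrings(pts2))
            for g in getattr(shapely.polygonize([lines]), "geoms", []):
                polys.append(g)
        if not polys:
            continue
        union = shapely.make_valid(shapely.union_all(polys))
        occ[:, :, k] = shapely.contains_xy(
            union, xg.ravel(), yg.ravel()
        ).reshape(nx, ny)
    return VoxelMask(occ, voxel_size, origin)


def voxelize_pair(
    mesh1: TriangleMesh,
    pose1: RigidTransform | None,
    mesh2: TriangleMesh,
    pose2: RigidTransform | None,
    voxel_size: float = DEFAULT_VOXEL_MM,
) -> tuple[VoxelMask, VoxelMask]:
    """Voxelise two posed meshes on one shared grid covering both."""
    v1 = mesh1.vertices if pose1 is None else pose1.apply(mesh1.vertices)
    v2 = mesh2.vertices if pose2 is None else pose2.apply(mesh2.vertices)
    allv = np.vstack([v1, v2])
    bounds = np.vstack([allv.min(axis=0), allv.max(axis=0)])
    origin, shape = _grid_from_bounds(bounds, voxel_size)
    return (
        voxelize(mesh1, pose1, voxel_size, origin, shape),
        voxelize(mesh2, pose2, voxel_size, origin, shape),
    )


def dice(x: VoxelMask, y: VoxelMask) -> float:
    """Dice similarity index of two occupancy masks on the same grid."""
    if not x.same_grid(y):
        raise ValueError("voxel grids do not match (size/origin/shape)")
    nx, ny = x.count, y.count
    if nx == 0 and ny == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int((x.occupancy & y.occupancy).sum())
    return 2.0 * inter / (nx + ny)


# ---------------------------------------------------------------------------
# Exact point-to-surface distances

def _point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from each point to its own triangle (vectorised
    region decomposition; points and tri are matched row-wise)."""
    B, E0, E1 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    D = B - points
    a = np.einsum("ij,ij->i", E0, E0)
    b = np.einsum("ij,ij->i", E0, E1)
    c = np.einsum("ij,ij->i", E1, E1)
    d = np.einsum("ij,ij->i", E0, D)
    e = np.einsum("ij,ij->i", E1, D)
    det = np.maximum(a * c - b * b, 1e-30)
    s = b * e - c * d
    t = b * d - a * e
    # interior case
    si = s / det
    ti = t / det
    # clamp via the standard 7-region case analysis, vectorised
    s_out = np.clip(si, 0.0, 1.0)
    t_out = np.clip(ti, 0.0, 1.0)
    inside = (si >= 0) & (ti >= 0) & (si + ti <= 1)
    # edge s+t=1
    su = np.clip((c + e - b - d) / np.maximum(a - 2 * b + c, 1e-30), 0.0, 1.0)
    # edge t=0
    s0 = np.clip(-d / np.maximum(a, 1e-30), 0.0, 1.0)
    # edge s=0
    t0 = np.clip(-e / np.maximum(c, 1e-30), 0.0, 1.0)

    cand_s = np.stack([np.where(inside, si, np.nan), s0, np.zeros_like(s0), su])
    cand_t = np.stack([np.where(inside, ti, np.nan), np.zeros_like(t0), t0, 1.0 - su])
    # evaluate squared distance for each candidate, take the min
    best = np.full(len(points), np.inf)
    for cs, ct in zip(cand_s, cand_t):
        valid = ~np.isnan(cs)
        P = B + cs[:, None] * E0 + ct[:, None] * E1
        d2 = np.einsum("ij,ij->i", P - points, P - points)
        d2 = np.where(valid, d2, np.inf)
        best = np.minimum(best, d2)
    return np.sqrt(best)


def point_surface_distances(points: np.ndarray, surface: TriangleMesh) -> np.ndarray:
    """Exact distance from each query point to the triangle surface.

    Candidate triangles are pruned with a KD-tree on triangle centroids
    plus a circumradius bound, which guarantees the exact nearest triangle
    is always among the candidates.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = surface.triangles
    centroids = tri.mean(axis=1)
    r_max = np.linalg.norm(tri - centroids[:, None, :], axis=2).max()
    # tight upper bound from the nearest mesh vertex; any triangle whose
    # centroid lies farther than that bound plus the largest circumradius
    # cannot contain the true closest point
    d_v = cKDTree(surface.vertices).query(points)[0]
    tree = cKDTree(centroids)
    balls = tree.query_ball_point(points, d_v + r_max + 1e-9)
    counts = np.fromiter((len(b) for b in balls), dtype=np.int64, count=len(balls))
    if counts.min() == 0:  # can't happen geometrically, but be safe
        fix = np.where(counts == 0)[0]
        near = tree.query(points[fix])[1]
        for i, t in zip(fix, np.atleast_1d(near)):
            balls[i] = [int(t)]
            counts[i] = 1
    flat_tri = np.concatenate([np.asarray(b, dtype=np.int64) for b in balls])
    flat_pts = np.repeat(points, counts, axis=0)
    d = _point_triangle_distance(flat_pts, tri[flat_tri])
    best = np.full(len(points), np.inf)
    owner = np.repeat(np.arange(len(points)), counts)
    np.minimum.at(best, owner, d)
    return best


def sample_surface(
    mesh: TriangleMesh, samples_per_mm2: float, rng: np.random.Generator
) -> np.ndarray:
    """Stratified area-proportional surface sampling: each triangle gets
    ``area * density`` samples (fractional part resolved by a Bernoulli
    draw), placed uniformly by barycentric coordinates."""
    if samples_per_mm2 <= 0:
        raise ValueError("samples_per_mm2 must be positive")
    areas = mesh.face_areas
    expect = areas * samples_per_mm2
    n_tri = np.floor(expect).astype(int)
    n_tri += rng.random(len(areas)) < (expect - n_tri)
    total = int(n_tri.sum())
    if total == 0:  # tiny surfaces: fall back to one sample on the largest
        n_tri[np.argmax(areas)] = 1
        total = 1
    face_idx = np.repeat(np.arange(len(areas)), n_tri)
    r1 = np.sqrt(rng.random(total))
    r2 = rng.random(total)
    tri = mesh.triangles[face_idx]
    return (
        (1 - r1)[:, None] * tri[:, 0]
        + (r1 * (1 - r2))[:, None] * tri[:, 1]
        + (r1 * r2)[:, None] * tri[:, 2]
    )


def mean_surface_distance(
    s1: TriangleMesh,
    s2: TriangleMesh,
    samples_per_mm2: float = 10.0,
    seed: int = 0,
    symmetric: bool = False,
) -> float:
    """Area-weighted mean of exact point-to-surface distances from S1 to
    S2 (one-sided by definition); ``symmetric=True`` returns the max of
    the two one-sided means."""
    if s1.area <= 0 or s2.area <= 0:
        raise ValueError("surfaces must have positive area")
    rng = np.random.default_rng(seed)
    pts = sample_surface(s1, samples_per_mm2, rng)
    d12 = float(point_surface_distances(pts, s2).mean())
    if not symmetric:
        return d12
    pts2 = sample_surface(s2, samples_per_mm2, rng)
    d21 = float(point_surface_distances(pts2, s1).mean())
    return max(d12, d21)


def hausdorff_max(
    s1: TriangleMesh,
    s2: TriangleMesh,
    samples_per_mm2: float = 10.0,
    seed: int = 0,
) -> float:
    """Symmetrised maximum surface distance, estimated over stratified
    samples plus all mesh vertices."""
    if s1.area <= 0 or s2.area <= 0:
        raise ValueError("surfaces must have positive area")
    rng = np.random.default_rng(seed)
    p1 = np.vstack([sample_surface(s1, samples_per_mm2, rng), s1.vertices])
    p2 = np.vstack([sample_surface(s2, samples_per_mm2, rng), s2.vertices])
    d12 = point_surface_distances(p1, s2).max()
    d21 = point_surface_distances(p2, s1).max()
    return float(max(d12, d21))


# ---------------------------------------------------------------------------
# Intraclass correlation

@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    variant: str
    n_cases: int
    n_raters: int

    def __iter__(self):  # (estimate, (low, high)) unpacking convenience
        return iter((self.estimate, (self.ci_low, self.ci_high)))


def icc(ratings, variant: str = "single_absolute_2way", ci: float = 0.95) -> ICCResult:
    """Two-way mixed-effects, absolute-agreement intraclass correlation.

    ``variant`` selects the single-measurement form ICC(A,1) (used for
    intra-rater comparisons) or the mean-of-k form ICC(A,k) (inter-rater,
    typically k = 2).  Confidence limits follow the standard F-based
    construction for absolute agreement (McGraw & Wong).
    """
    M = np.asarray(ratings, dtype=float)
    if M.ndim != 2:
        raise ValueError("ratings must be a cases x raters matrix")
    n, k = M.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 cases and 2 raters")
    if np.isnan(M).any():
        raise ValueError("missing ratings are not supported")
    if variant not in ("single_absolute_2way", "mean_k_absolute_2way"):
        raise ValueError(f"unknown ICC variant {variant!r}")

    grand = M.mean()
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    if np.allclose(row_means.var(), 0.0, atol=1e-15):
        raise ValueError("zero between-case variance: ICC undefined")

    SSR = k * ((row_means - grand) ** 2).sum()
    SSC = n * ((col_means - grand) ** 2).sum()
    SST = ((M - grand) ** 2).sum()
    SSE = SST - SSR - SSC
    MSR = SSR / (n - 1)
    MSC = SSC / (k - 1)
    MSE = SSE / ((n - 1) * (k - 1))

    alpha = 1.0 - ci
    if variant == "single_absolute_2way":
        est = (MSR - MSE) / (MSR + (k - 1) * MSE + k * (MSC - MSE) / n)
        a = k * est / (n * (1.0 - est)) if est < 1.0 else np.inf
        b = 1.0 + k * est * (n - 1) / (n * (1.0 - est)) if est < 1.0 else np.inf
        if np.isfinite(a):
            v = (a * MSC + b * MSE) ** 2 / (
                (a * MSC) ** 2 / (k - 1) + (b * MSE) ** 2 / ((n - 1) * (k - 1))
            )
            FL = stats.f.ppf(1 - alpha / 2, n - 1, v)
            FU = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (MSR - FL * MSE) / (
                FL * (k * MSC + (k * n - k - n) * MSE) + n * MSR
            )
            hi = n * (FU * MSR - MSE) / (
                k * MSC + (k * n - k - n) * MSE + n * FU * MSR
            )
        else:
            lo = hi = 1.0
    else:
        est = (MSR - MSE) / (MSR + (MSC - MSE) / n)
        single = (MSR - MSE) / (MSR + (k - 1) * MSE + k * (MSC - MSE) / n)
        a = k * single / (n * (1.0 - single)) if single < 1.0 else np.inf
        b = 1.0 + k * single * (n - 1) / (n * (1.0 - single)) if single < 1.0 else np.inf
        if np.isfinite(a):
            v = (a * MSC + b * MSE) ** 2 / (
                (a * MSC) ** 2 / (k - 1) + (b * MSE) ** 2 / ((n - 1) * (k - 1))
            )
            FL = stats.f.ppf(1 - alpha / 2, n - 1, v)
            FU = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo1 = n * (MSR - FL * MSE) / (
                FL * (k * MSC + (k * n - k - n) * MSE) + n * MSR
            )
            hi1 = n * (FU * MSR - MSE) / (
                k * MSC + (k * n - k - n) * MSE + n * FU * MSR
            )
            # Spearman-Brown step up from the single-measure limits
            lo = lo1 * k / (1 + (k - 1) * lo1)
            hi = hi1 * k / (1 + (k - 1) * hi1)
        else:
            lo = hi = 1.0
    return ICCResult(float(est), float(lo), float(hi), variant, n, k)


# ---------------------------------------------------------------------------
# Agreement report

@dataclass
class AgreementReport:
    """Comparison of two matched sets of registered spines.

    ``distances`` is a cases x 6 (L1..S) table of one-sided mean surface
    distances between corresponding registered vertebrae; ``dsi``
    likewise for Dice (if volumes were computed); ``icc_angles`` holds one
    ICC per angle series (five segments + LL).  ``cumulative`` is the
    empirical cumulative fraction of vertebra pairs below each distance.
    """

    distances: pd.DataFrame
    icc_angles: dict[str, ICCResult]
    dsi: pd.DataFrame | None = None
    comparison: str = ""

    @property
    def fraction_below(self):
        def f(threshold_mm: float) -> float:
            vals = self.distances.to_numpy().ravel()
            return float((vals < threshold_mm).mean())

        return f

    def cumulative(self) -> pd.DataFrame:
        vals = np.sort(self.distances.to_numpy().ravel())
        frac = np.arange(1, len(vals) + 1) / len(vals)
        return pd.DataFrame({"distance_mm": vals, "fraction": frac})

    def summary(self) -> str:
        lines = [f"Agreement report {self.comparison}".rstrip()]
        lines.append(
            f"  mean surface distance : {self.distances.to_numpy().mean():.4f} mm "
            f"(max {self.distances.to_numpy().max():.4f})"
        )
        lines.append(
            f"  pairs < 1 mm          : {100 * self.fraction_below(1.0):.1f}%"
        )
        if self.dsi is not None:
            lines.append(
                f"  Dice (min / mean)     : {self.dsi.to_numpy().min():.4f} / "
                f"{self.dsi.to_numpy().mean():.4f}"
            )
        for name, r in self.icc_angles.items():
            lines.append(
                f"  ICC({name:<5})          : {r.estimate:.3f} "
                f"[{r.ci_low:.3f}, {r.ci_high:.3f}]"
            )
        return "\n".join(lines)


def build_agreement_report(
    models1,
    models2,
    angles1,
    angles2,
    samples_per_mm2: float = 2.0,
    seed: int = 0,
    voxel_size: float | None = None,
    symmetric: bool = False,
    icc_variant: str = "single_absolute_2way",
    comparison: str = "",
) -> AgreementReport:
    """Compare two matched registration sets case by case.

    ``models1``/``models2`` are equal-length lists of registered
    :class:`SpineModel`; ``angles1``/``angles2`` the matching
    :class:`AngleSet` measurements.  Computes per-vertebra mean surface
    distances (Dice too when ``voxel_size`` is given) and per-angle ICCs
    across the two sets.
    """
    if len(models1) != len(models2) or len(angles1) != len(angles2):
        raise ValueError("the two sets must have matching lengths")
    rows_d, rows_dsi = [], []
    for i, (m1, m2) in enumerate(zip(models1, models2)):
        row_d, row_dsi = {}, {}
        for v1, v2 in zip(m1, m2):
            if v1.label != v2.label:
                raise ValueError(f"case {i}: vertebra labels mismatch")
            row_d[v1.label] = mean_surface_distance(
                v1.posed_mesh(),
                v2.posed_mesh(),
                samples_per_mm2,
                seed=seed + i,
                symmetric=symmetric,
            )
            if voxel_size is not None:
                a, b = voxelize_pair(
                    v1.mesh, v1.transform, v2.mesh, v2.transform, voxel_size
                )
                row_dsi[v1.label] = dice(a, b)
        rows_d.append(row_d)
        if voxel_size is not None:
            rows_dsi.append(row_dsi)
    distances = pd.DataFrame(rows_d, columns=list(LABELS))
    dsi = pd.DataFrame(rows_dsi, columns=list(LABELS)) if voxel_size else None

    icc_angles = {}
    names = [f"{LABELS[i]}{LABELS[i + 1]}" for i in range(5)] + ["LL"]
    arr1 = np.array([list(a) for a in angles1])
    arr2 = np.array([list(a) for a in angles2])
    for j, name in enumerate(names):
        icc_angles[name] = icc(
            np.column_stack([arr1[:, j], arr2[:, j]]), icc_variant
        )
    return AgreementReport(distances, icc_angles, dsi, comparison)
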