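"""2D contours on detector planes.

Contours are always stored in detector millimetre coordinates, never in
pixels.  A :class:`Contour2D` is a single open or closed polyline; a
:class:`ContourObject` groups several open sections under one vertebra
label, mirroring the way an investigator collects only the well-defined
edges (vertebral body, process margins) into one contour object per
vertebra and view.
"""

from __future__ import annotations

import json

import numpy as np
import shapely
from scipy import ndimage

__all__ = [
    "Contour2D",
    "ContourObject",
    "snap_contour",
    "contour_from_silhouette",
    "point_to_contour_distance",
]


class Contour2D:
    """Ordered 2D points (mm) forming an open polyline or a closed ring."""

    def __init__(self, points, closed: bool = False, label=None, view=None):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        # drop consecutive duplicates
        if len(pts) > 1:
            keep = np.ones(len(pts), dtype=bool)
            keep[1:] = np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12
            pts = pts[keep]
        if closed and len(pts) > 2 and np.linalg.norm(pts[0] - pts[-1]) < 1e-12:
            pts = pts[:-1]
        n_min = 3 if closed else 2
        if len(pts) < n_min:
            raise ValueError(f"need at least {n_min} distinct points")
        self.points = pts
        self.points.setflags(write=False)
        self.closed = bool(closed)
        self.label = label
        self.view = view
        self._geom = None

    def __len__(self):
        return len(self.points)

    @property
    def geometry(self):
        """Shapely LinearRing (closed) or LineString (open), cached."""
        if self._geom is None:
            if self.closed:
                self._geom = shapely.LinearRing(self.points)
            else:
                self._geom = shapely.LineString(self.points)
        return self._geom

    @property
    def length(self) -> float:
        return float(self.geometry.length)

    def densified(self, step: float) -> np.ndarray:
        """Points resampled along the polyline at spacing <= ``step`` mm
        (original vertices are retained)."""
        if step <= 0:
            raise ValueError("step must be positive")
        g = shapely.segmentize(self.geometry, step)
        pts = np.asarray(g.coords)
        if self.closed:
            pts = pts[:-1]
        return pts

    def transformed(self, rotation_deg: float = 0.0, translation=(0.0, 0.0)) -> "Contour2D":
        """Planar rigid motion of the contour (for equivariance checks)."""
        a = np.deg2rad(rotation_deg)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return Contour2D(
            self.points @ R.T + np.asarray(translation, dtype=float),
            self.closed,
            self.label,
            self.view,
        )

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "view": self.view,
            "closed": self.closed,
            "points": [[float(a), float(b)] for a, b in self.points],
        }

    @staticmethod
    def from_dict(d: dict) -> "Contour2D":
        return Contour2D(d["points"], bool(d["closed"]), d.get("label"), d.get("view"))

    def __repr__(self):
        kind = "closed" if self.closed else "open"
        return f"Contour2D({kind}, n={len(self.points)}, label={self.label!r})"


class ContourObject:
    """A flat list of contour sections sharing one label and view."""

    def __init__(self, segments, label=None, view=None):
        segments = list(segments)
        if not segments:
            raise ValueError("contour object needs at least one segment")
        self.segments = segments
        self.label = label if label is not None else segments[0].label
        self.view = view if view is not None else segments[0].view

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def densified(self, step: float) -> np.ndarray:
        return np.vstack([s.densified(step) for s in self.segments])

    @property
    def length(self) -> float:
        return sum(s.length for s in self.segments)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "view": self.view,
            "segments": [s.to_dict() for s in self.segments],
        }

    @staticmethod
    def from_dict(d: dict) -> "ContourObject":
        return ContourObject(
            [Contour2D.from_dict(s) for s in d["segments"]],
            d.get("label"),
            d.get("view"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def as_contour_object(target) -> ContourObject:
    """Normalise Contour2D / list / ContourObject into a ContourObject."""
    if isinstance(target, ContourObject):
        return target
    if isinstance(target, Contour2D):
        return ContourObject([target])
    return ContourObject(list(target))


# ---------------------------------------------------------------------------
# Gradient snapping

def _catmull_rom(control: np.ndarray, step: float) -> np.ndarray:
    """Centripetal-free uniform Catmull-Rom curve through the control
    points, sampled roughly every ``step`` mm; control points are
    interpolated exactly."""
    if len(control) < 3:
        return _densify_polyline(control, step)
    P = np.vstack([control[0], control, control[-1]])
    out = [control[0]]
    for i in range(1, len(P) - 2):
        p0, p1, p2, p3 = P[i - 1], P[i], P[i + 1], P[i + 2]
        seg_len = np.linalg.norm(p2 - p1)
        n = max(int(np.ceil(seg_len / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        a = 2 * p1
        b = p2 - p0
        c = 2 * p0 - 5 * p1 + 4 * p2 - p3
        d = -p0 + 3 * p1 - 3 * p2 + p3
        pts = 0.5 * (a + b * t + c * t**2 + d * t**3)
        out.append(pts)
    return np.vstack(out)


def _densify_polyline(control: np.ndarray, step: float) -> np.ndarray:
    out = [control[0]]
    for a, b in zip(control[:-1], control[1:]):
        n = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        out.append(a + t * (b - a))
    return np.vstack(out)


def snap_contour(
    image,
    control_points,
    search_radius: float = 3.0,
    densify_step: float = 0.5,
    spline: bool = True,
    sigma_px: float = 1.0,
    threshold_frac: float = 0.1,
    label=None,
) -> Contour2D:
    """Attract a control-point polyline to nearby image gradients.

    The curve through the control points (Catmull-Rom spline by default,
    straight segments with ``spline=False``) is densified at
    ``densify_step`` mm and every sample — control points included — is
    moved along the local curve normal, within ``+/-search_radius`` mm, to
    the position of maximum Gaussian-derivative gradient magnitude
    (sigma = ``sigma_px`` pixels).  Samples with no gradient response above
    ``threshold_frac`` times the image's maximum gradient stay in place,
    so the tool degrades gracefully to plain lines/splines in flat regions.
    """
    control = np.asarray(control_points, dtype=float)
    if control.ndim != 2 or control.shape[1] != 2 or len(control) < 2:
        raise ValueError("need at least two 2D control points")
    if search_radius <= 0:
        raise ValueError("search_radius must be positive")
    if not image.contains_mm(control).all():
        raise ValueError("control points must lie inside the image")

    base = (_catmull_rom if spline else _densify_polyline)(control, densify_step)

    grad = ndimage.gaussian_gradient_magnitude(image.pixels.astype(float), sigma_px)
    gmax = grad.max()
    threshold = threshold_frac * gmax if gmax > 0 else np.inf

    # local normals from central-difference tangents
    tang = np.gradient(base, axis=0)
    norms = np.linalg.norm(tang, axis=1)
    norms[norms == 0] = 1.0
    tang = tang / norms[:, None]
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    # sample gradient along each normal at quarter-pixel resolution
    step_mm = image.pixel_spacing / 4.0
    offsets = np.arange(-search_radius, search_radius + step_mm / 2, step_mm)
    cand = base[:, None, :] + offsets[None, :, None] * normal[:, None, :]
    rc = image.mm_to_rowcol(cand.reshape(-1, 2)).reshape(len(base), len(offsets), 2)
    vals = ndimage.map_coordinates(
        grad, [rc[..., 0].ravel(), rc[..., 1].ravel()], order=1, mode="constant"
    ).reshape(len(base), len(offsets))

    best = vals.argmax(axis=1)
    move = vals[np.arange(len(base)), best] > threshold
    snapped = base.copy()
    snapped[move] += offsets[best[move], None] * normal[move]
    view = getattr(image, "view", None)
    return Contour2D(snapped, closed=False, label=label, view=view)


# ---------------------------------------------------------------------------
# Partial-contour selection

def contour_from_silhouette(sil: Contour2D, segments) -> ContourObject:
    """Extract sub-polylines of a closed silhouette as an open
    multi-section contour object.

    ``segments`` is a list of half-open vertex index ranges
    ``(start, stop)`` over the silhouette's points; ``start > stop`` wraps
    around the ring.  A single range covering every vertex returns the
    closed silhouette unchanged.  Emulates an investigator tracing only
    the reliable edges of the radiograph.
    """
    if not sil.closed:
        raise ValueError("silhouette must be a closed contour")
    n = len(sil.points)
    covered = np.zeros(n, dtype=bool)
    parts = []
    for start, stop in segments:
        if not (0 <= start < n and 0 <= stop <= n):
            raise ValueError(f"range ({start}, {stop}) out of bounds for n={n}")
        idx = (
            np.arange(start, stop)
            if stop >= start
            else np.concatenate([np.arange(start, n), np.arange(0, stop)])
        )
        if len(idx) == 0:
            raise ValueError("empty index range")
        if covered[idx].any():
            raise ValueError("index ranges overlap")
        covered[idx] = True
        parts.append(idx)
    if len(parts) == 1 and len(parts[0]) == n:
        return ContourObject([sil])
    out = []
    for idx in parts:
        pts = sil.points[idx]
        if len(pts) < 2:
            raise ValueError("each selected section needs at least 2 points")
        out.append(Contour2D(pts, closed=False, label=sil.label, view=sil.view))
    return ContourObject(out, label=sil.label, view=sil.view)


def point_to_contour_distance(p, contour) -> float:
    """Euclidean distance (mm) from a point to the nearest point on any
    contour segment (segments are polylines, not vertex sets)."""
    pt = shapely.Point(np.asarray(p, dtype=float))
    if isinstance(contour, ContourObject):
        return float(min(seg.geometry.distance(pt) for seg in contour))
    return float(contour.geometry.distance(pt))
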