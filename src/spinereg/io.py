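"""File formats and case bundles.

Meshes travel as STL (binary or ASCII) named ``<case>_<label>.stl``;
poses, calibration and contours as JSON; angle tables and metric reports
as CSV; radiographs as 16-bit PNG.  Everything a run needs is plain text
or a standard imaging format, so results can be inspected and re-used by
other tools.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .alignment import AngleSet
from .contours import Contour2D, ContourObject
from .geometry import LABELS, RigidTransform, TriangleMesh
from .projection import BiplanarEnvironment, RadiographImage

__all__ = [
    "read_stl",
    "write_stl",
    "read_environment",
    "write_environment",
    "read_contours",
    "write_contours",
    "read_pose",
    "write_pose",
    "read_radiograph",
    "write_radiograph",
    "angles_to_csv",
    "CaseBundle",
]


def _label_from_path(path: Path) -> str | None:
    stem = path.stem
    tail = stem.rsplit("_", 1)[-1].upper()
    return tail if tail in LABELS else None


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL; the vertebra label is taken from the
    ``<case>_<label>.stl`` filename convention when present."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) >= 84 and not data.lstrip()[:5].lower() == b"solid":
        # quick structural validation of binary STL so truncation is
        # reported with a byte offset rather than a cryptic parse error
        (n_tri,) = struct.unpack("<I", data[80:84])
        expected = 84 + 50 * n_tri
        if len(data) < expected:
            raise ValueError(
                f"{path}: truncated binary STL at byte {len(data)} "
                f"(expected {expected} bytes for {n_tri} facets)"
            )
    try:
        tm = trimesh.load(path, file_type="stl", process=False)
    except Exception as exc:
        raise ValueError(f"{path}: failed to parse STL ({exc})") from exc
    if not hasattr(tm, "vertices") or len(getattr(tm, "faces", [])) == 0:
        raise ValueError(f"{path}: STL contains no triangles")
    # merge duplicated vertices (STL stores each facet independently)
    tm.merge_vertices()
    return TriangleMesh(tm.vertices, tm.faces, label=_label_from_path(path))


def write_stl(mesh: TriangleMesh, path, binary: bool = True) -> None:
    path = Path(path)
    tm = trimesh.Trimesh(mesh.vertices.copy(), mesh.faces.copy(), process=False)
    tm.export(path, file_type="stl" if binary else "stl_ascii")


def write_environment(env: BiplanarEnvironment, path) -> None:
    Path(path).write_text(json.dumps(env.to_dict(), indent=2))


def read_environment(path) -> BiplanarEnvironment:
    return BiplanarEnvironment.from_dict(json.loads(Path(path).read_text()))


def write_contours(contours: dict, path) -> None:
    """``contours`` maps label -> view -> Contour2D | ContourObject."""
    out = {}
    for label, per_view in contours.items():
        out[label] = {}
        for view, c in per_view.items():
            d = c.to_dict()
            d["kind"] = "object" if isinstance(c, ContourObject) else "contour"
            out[label][view] = d
    Path(path).write_text(json.dumps(out, indent=2))


def read_contours(path) -> dict:
    raw = json.loads(Path(path).read_text())
    out = {}
    for label, per_view in raw.items():
        out[label] = {}
        for view, d in per_view.items():
            if d.get("kind") == "object" or "segments" in d:
                out[label][view] = ContourObject.from_dict(d)
            else:
                out[label][view] = Contour2D.from_dict(d)
    return out


def write_pose(t: RigidTransform, path) -> None:
    Path(path).write_text(t.to_json())


def read_pose(path) -> RigidTransform:
    return RigidTransform.from_json(Path(path).read_text())


def write_radiograph(img: RadiographImage, path) -> None:
    """16-bit PNG; float images are clipped to [0, 1] and scaled."""
    import imageio.v3 as iio

    px = img.pixels
    if px.dtype != np.uint16:
        px = (np.clip(px, 0.0, 1.0) * 65535).astype(np.uint16)
    iio.imwrite(Path(path), px)
    meta = {"pixel_spacing": img.pixel_spacing, "view": img.view}
    Path(path).with_suffix(".json").write_text(json.dumps(meta))


def read_radiograph(path) -> RadiographImage:
    import imageio.v3 as iio

    path = Path(path)
    px = iio.imread(path).astype(float) / 65535.0
    meta = json.loads(path.with_suffix(".json").read_text())
    return RadiographImage(px, float(meta["pixel_spacing"]), meta["view"])


def angles_to_csv(rows: dict[str, AngleSet], path) -> None:
    """One CSV row per case: case, L1L2 .. L5S, LL (degrees)."""
    import pandas as pd

    names = [f"{LABELS[i]}{LABELS[i + 1]}" for i in range(5)] + ["LL"]
    table = []
    for case, angles in rows.items():
        row = {"case": case}
        row.update(dict(zip(names, angles)))
        table.append(row)
    pd.DataFrame(table, columns=["case"] + names).to_csv(path, index=False)


@dataclass
class CaseBundle:
    """Paths making up one registration case on disk."""

    case_id: str
    mesh_paths: dict[str, Path]
    env_path: Path
    contour_path: Path
    radiograph_paths: dict[str, Path] = field(default_factory=dict)
    ground_truth_path: Path | None = None

    def validate(self, for_registration: bool = True) -> None:
        missing = [str(p) for p in self._all_paths() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"case {self.case_id}: missing {missing}")
        if for_registration:
            absent = [lbl for lbl in LABELS if lbl not in self.mesh_paths]
            if absent:
                raise ValueError(f"case {self.case_id}: no meshes for {absent}")

    def _all_paths(self):
        yield from self.mesh_paths.values()
        yield self.env_path
        yield self.contour_path
        yield from self.radiograph_paths.values()
        if self.ground_truth_path is not None:
            yield self.ground_truth_path

    @staticmethod
    def discover(directory, case_id: str = "case") -> "CaseBundle":
        """Build a bundle from a conventional case directory."""
        d = Path(directory)
        meshes = {}
        for p in sorted(d.glob("*.stl")):
            lbl = _label_from_path(p)
            if lbl:
                meshes[lbl] = p
        gt = d / "ground_truth.json"
        return CaseBundle(
            case_id=case_id,
            mesh_paths=meshes,
            env_path=d / "environment.json",
            contour_path=d / "contours.json",
            radiograph_paths={
                p.stem: p for p in sorted(d.glob("*.png")) if p.stem in ("frontal", "sagittal")
            },
            ground_truth_path=gt if gt.exists() else None,
        )
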