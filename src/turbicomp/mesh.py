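"""Convex-hull complexity indices for triangle meshes.

Turbinal bones are thin, scrolled bony sheets; how much sheet is packed
into how little envelope is the morphological quantity of interest.  Two
dimensionless indices capture it:

* ``CHAR`` (convex hull area ratio): mesh surface area divided by the
  surface area of its 3D convex hull.  A convex shape scores 1; folding
  raises SA without raising the hull area, so CHAR grows with complexity.
* ``CHNSI`` (convex hull normalised shape index): ``F * sqrt(SA) /
  cbrt(CHV)`` where ``CHV`` is the hull volume and ``F`` is fixed so a
  sphere scores exactly 1.  It asks how much surface is carried per unit
  of enclosing volume, normalised to be scale free.

Both indices are invariant under uniform scaling and rigid motion, and
carry the mesh's length units through opaquely (the indices themselves are
dimensionless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import trimesh as _trimesh
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "F_SPHERE",
    "TriangleMesh",
    "MeshError",
    "OpenMeshError",
    "DegenerateMeshError",
    "load_mesh",
    "save_mesh",
    "merge_meshes",
    "surface_area",
    "convex_hull",
    "char_index",
    "chnsi_index",
    "complexity_report",
]

#: Normalisation constant of CHNSI: cbrt(4*pi/3) / (2*sqrt(pi)).
#: For a sphere SA = 4*pi*r^2 and CHV = (4/3)*pi*r^3, so
#: F * sqrt(SA) / cbrt(CHV) = 1 for every radius.
F_SPHERE: float = (4.0 * math.pi / 3.0) ** (1.0 / 3.0) / (2.0 * math.sqrt(math.pi))


class MeshError(ValueError):
    """Invalid mesh input."""


class OpenMeshError(MeshError):
    """The operation needs a closed mesh (well-defined enclosed volume)."""


class DegenerateMeshError(MeshError):
    """Mesh is degenerate for the requested operation (e.g. coplanar)."""


@dataclass
class TriangleMesh:
    """A triangle mesh: ``vertices`` (n, 3) float array, ``faces`` (m, 3) int array."""

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError(f"{self.label or 'mesh'}: face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_closed(self) -> bool:
        """True when every undirected edge is shared by exactly two faces."""
        if self.n_faces == 0:
            return False
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def deduplicated(self, tol: float = 0.0) -> "TriangleMesh":
        """Merge duplicate vertices and drop unreferenced ones.

        CT-derived meshes routinely carry both artefacts; hulling and the
        closedness check want them gone.
        """
        if tol > 0:
            key = np.round(self.vertices / tol).astype(np.int64)
        else:
            key = self.vertices
        _, first, inverse = np.unique(
            key, axis=0, return_index=True, return_inverse=True
        )
        faces = inverse[self.faces]
        used = np.unique(faces)
        remap = -np.ones(len(first), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return TriangleMesh(self.vertices[first][used], remap[faces], self.label)

    def scaled(self, k: float) -> "TriangleMesh":
        return TriangleMesh(self.vertices * float(k), self.faces.copy(), self.label)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices @ np.asarray(rotation).T + np.asarray(translation),
            self.faces.copy(),
            self.label,
        )

    def to_trimesh(self) -> "_trimesh.Trimesh":
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)

    @classmethod
    def from_trimesh(cls, mesh: "_trimesh.Trimesh", label: str = "") -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), label)


def load_mesh(path: str | Path, label: str | None = None) -> TriangleMesh:
    """Read an OFF / PLY / STL file (ascii or binary) into a :class:`TriangleMesh`."""
    path = Path(path)
    tm = _trimesh.load_mesh(str(path), process=False)
    if isinstance(tm, _trimesh.Scene):  # multi-body files
        tm = _trimesh.util.concatenate(list(tm.geometry.values()))
    return TriangleMesh.from_trimesh(tm, label if label is not None else path.stem)


def save_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    mesh.to_trimesh().export(str(path))


def merge_meshes(meshes: Sequence[TriangleMesh], label: str = "") -> TriangleMesh:
    """Concatenate meshes into one (used to pool a turbinal group before indexing)."""
    if not meshes:
        raise MeshError("cannot merge an empty list of meshes")
    verts, faces, offset = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        offset += m.n_vertices
    return TriangleMesh(np.vstack(verts), np.vstack(faces), label)


def surface_area(mesh: TriangleMesh) -> float:
    """Total area of all triangles (both the mesh's sides of a closed shell count once)."""
    if mesh.n_faces == 0:
        raise DegenerateMeshError(f"{mesh.label or 'mesh'}: no faces, area undefined")
    v = mesh.vertices
    a = v[mesh.faces[:, 1]] - v[mesh.faces[:, 0]]
    b = v[mesh.faces[:, 2]] - v[mesh.faces[:, 0]]
    return float(0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum())


def convex_hull(mesh: TriangleMesh) -> tuple[TriangleMesh, float, float]:
    """3D convex hull of the mesh's vertices.

    Returns ``(hull_mesh, hull_area, hull_volume)``.  Uses an exact
    quickhull with a joggle fallback for the nearly-coplanar vertex sheets
    that voxel-derived meshes produce.  Degenerate (coplanar or collinear)
    input raises :class:`DegenerateMeshError`.
    """
    pts = np.unique(mesh.vertices, axis=0)  # duplicates merged; all points count
    if len(pts) < 4:
        raise DegenerateMeshError(
            f"{mesh.label or 'mesh'}: need >=4 distinct vertices for a 3D hull"
        )
    centred = pts - pts.mean(axis=0)
    rank = np.linalg.matrix_rank(centred, tol=1e-10 * max(1.0, np.abs(centred).max()))
    if rank < 3:
        kind = {0: "a point", 1: "collinear", 2: "coplanar"}[int(rank) if rank < 3 else 2]
        raise DegenerateMeshError(
            f"{mesh.label or 'mesh'}: vertices are {kind}; 3D hull undefined"
        )
    try:
        hull = ConvexHull(pts)
    except QhullError:
        hull = ConvexHull(pts, qhull_options="QJ")
    hull_mesh = TriangleMesh(
        pts[hull.vertices],
        np.searchsorted(hull.vertices, hull.simplices.ravel()).reshape(-1, 3),
        (mesh.label + ":hull") if mesh.label else "hull",
    )
    return hull_mesh, float(hull.area), float(hull.volume)


def char_index(mesh: TriangleMesh) -> float:
    """Convex hull area ratio: ``CHAR = SA / CHSA``.

    Defined for open and closed meshes alike; >= 1 for closed meshes since
    the hull is the smallest convex envelope.
    """
    sa = surface_area(mesh)
    _, chsa, _ = convex_hull(mesh)
    return sa / chsa


def chnsi_index(mesh: TriangleMesh) -> float:
    """Convex hull normalised shape index: ``CHNSI = F * sqrt(SA) / cbrt(CHV)``.

    Requires a closed mesh: the hull volume is only meaningful as an
    enclosure of a solid shape.
    """
    if not mesh.is_closed():
        raise OpenMeshError(
            f"{mesh.label or 'mesh'}: CHNSI needs a closed mesh (hull volume "
            "encloses a solid); CHAR remains available for open sheets"
        )
    sa = surface_area(mesh)
    _, _, chv = convex_hull(mesh)
    if chv <= 0:
        raise DegenerateMeshError(f"{mesh.label or 'mesh'}: zero hull volume")
    return F_SPHERE * math.sqrt(sa) / chv ** (1.0 / 3.0)


def complexity_report(meshes: Iterable[TriangleMesh]) -> pd.DataFrame:
    """Per-mesh table of SA, CHSA, CHV, CHAR, CHNSI (rows ordered by label).

    A failure on one mesh is recorded in its row's ``error`` column and does
    not abort the batch.
    """
    rows = []
    for m in meshes:
        row: dict = {
            "label": m.label,
            "SA": np.nan,
            "CHSA": np.nan,
            "CHV": np.nan,
            "CHAR": np.nan,
            "CHNSI": np.nan,
            "closed": m.is_closed() if m.n_faces else False,
            "n_vertices": m.n_vertices,
            "n_faces": m.n_faces,
            "error": "",
        }
        try:
            row["SA"] = surface_area(m)
            _, row["CHSA"], row["CHV"] = convex_hull(m)
            row["CHAR"] = row["SA"] / row["CHSA"]
            if row["closed"]:
                row["CHNSI"] = F_SPHERE * math.sqrt(row["SA"]) / row["CHV"] ** (1 / 3)
            else:
                row["error"] = "open mesh: CHNSI undefined"
        except MeshError as exc:
            row["error"] = str(exc)
        rows.append(row)
    cols = ["label", "SA", "CHSA", "CHV", "CHAR", "CHNSI", "closed",
            "n_vertices", "n_faces", "error"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("label", kind="stable").reset_index(drop=True)
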