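"""Triangular surface meshes in mm and volume computation.

TriMesh is a light wrapper over :mod:`trimesh` that enforces the package's
structural invariants (0-based indices, no degenerate faces) and provides
the signed divergence-theorem volume used for cranial-capacity estimates.
"""

from __future__ import annotations

import numpy as np
import trimesh

__all__ = ["TriMesh", "mesh_volume"]


class MeshError(ValueError):
    pass


class TriMesh:
    """Triangular mesh: V x 3 vertices (mm), F x 3 0-based face indices."""

    def __init__(
        self,
        vertices: np.ndarray,
        faces: np.ndarray,
        validate: bool = True,
        merge_vertices: bool = False,
    ) -> None:
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise MeshError("vertices must be (V, 3)")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise MeshError("faces must be (F, 3)")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            raise MeshError("face indices out of range")
        tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
        if merge_vertices:
            tm.merge_vertices(merge_tex=True, merge_norm=True)
        if validate:
            areas = tm.area_faces
            degenerate = areas < 1e-12
            if degenerate.any():
                tm.update_faces(~degenerate)
        self._tm = tm

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriMesh":
        return cls(tm.vertices, tm.faces, validate=False)

    @property
    def vertices(self) -> np.ndarray:
        return np.asarray(self._tm.vertices)

    @property
    def faces(self) -> np.ndarray:
        return np.asarray(self._tm.faces)

    @property
    def watertight(self) -> bool:
        return bool(self._tm.is_watertight)

    @property
    def face_areas(self) -> np.ndarray:
        return np.asarray(self._tm.area_faces)

    @property
    def area(self) -> float:
        return float(self._tm.area)

    def as_trimesh(self) -> trimesh.Trimesh:
        return self._tm

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy(), validate=False)

    def with_vertices(self, vertices: np.ndarray) -> "TriMesh":
        """Same topology, new vertex positions (e.g. after a TPS warp)."""
        vertices = np.asarray(vertices, dtype=float)
        if vertices.shape != self.vertices.shape:
            raise MeshError("vertex array shape must be preserved")
        return TriMesh(vertices, self.faces.copy(), validate=False)

    def transformed(self, transform) -> "TriMesh":
        """Apply a SimilarityTransform to all vertices."""
        return self.with_vertices(transform.apply(self.vertices))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TriMesh({len(self.vertices)} vertices, {len(self.faces)} faces, "
            f"watertight={self.watertight})"
        )


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume of a watertight mesh, in cc (cm^3).

    Face orientation is repaired to a consistent outward convention before
    the signed divergence-theorem volume is taken; the result is returned
    positive and converted from mm^3 (1 cc = 1000 mm^3). Non-watertight
    meshes are rejected with the number of boundary edges.
    """
    tm = mesh.as_trimesh().copy()
    if not tm.is_watertight:
        edges = tm.edges_sorted
        unique, counts = np.unique(edges, axis=0, return_counts=True)
        n_boundary = int((counts != 2).sum())
        raise MeshError(
            f"mesh is not watertight ({n_boundary} edges not shared by exactly 2 faces)"
        )
    trimesh.repair.fix_normals(tm)
    volume_mm3 = abs(float(tm.volume))
    return volume_mm3 / 1000.0
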