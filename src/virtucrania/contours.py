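"""External cranial topology as contour polylines on parallel planes.

Closed polygonal chains are drawn where equidistant planes, set
perpendicular to the maximum-cranial-length axis (the glabella to
opisthocranion chord), intersect the cranial surface. The ordered stack
of contours — starting at the opisthocranion and marching toward the
glabella — maps vault features such as an occipital bun or lambdoid
flattening without committing to any landmark scheme on the back of the
vault.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .landmarks import LandmarkConfiguration
from .meshes import MeshError, TriMesh
from .procrustes import SimilarityTransform, opa_align

logger = logging.getLogger(__name__)

__all__ = ["SlicingFrame", "Polyline", "PlaneSection", "define_slicing_frame", "generate_polylines"]


@dataclass
class SlicingFrame:
    """Axis and ordered plane offsets for contour slicing."""

    axis: np.ndarray  # unit vector opisthocranion -> glabella
    origin: np.ndarray  # opisthocranion
    offsets: np.ndarray  # mm from the opisthocranion toward the glabella
    spacing: float
    alignment: SimilarityTransform | None = None  # optional pre-alignment

    def plane(self, offset: float) -> tuple[np.ndarray, np.ndarray]:
        """(origin, normal) of the slicing plane at the given offset."""
        return self.origin + offset * self.axis, self.axis


@dataclass
class Polyline:
    points: np.ndarray  # (n, 3); first == last when closed
    closed: bool

    @property
    def perimeter(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def centroid(self) -> np.ndarray:
        pts = self.points[:-1] if self.closed else self.points
        return pts.mean(axis=0)

    def area(self, normal: np.ndarray) -> float:
        """Enclosed planar area (shoelace in the section plane)."""
        if not self.closed:
            raise MeshError("area is defined for closed polylines only")
        pts = self.points[:-1]
        centre = pts.mean(axis=0)
        rel = pts - centre
        cross = np.cross(rel, np.roll(rel, -1, axis=0))
        return float(abs(0.5 * cross.sum(axis=0) @ (normal / np.linalg.norm(normal))))


@dataclass
class PlaneSection:
    offset_mm: float
    polylines: list[Polyline] = field(default_factory=list)


def define_slicing_frame(
    glabella: np.ndarray,
    opisthocranion: np.ndarray,
    spacing: float = 2.0,
    midline_landmarks: LandmarkConfiguration | None = None,
    reference_midline: LandmarkConfiguration | None = None,
) -> SlicingFrame:
    """Slicing frame perpendicular to the maximum-cranial-length axis.

    The axis is the unit glabella-to-opisthocranion chord; planes sit at
    offsets k * spacing measured from the opisthocranion toward the
    glabella, up to and including the chord length only when it is an
    exact multiple of the spacing. If a reference midline configuration
    (e.g. glabella/bregma/lambda of a reference specimen) is supplied
    together with the specimen's own, the rigid transform registering the
    specimen's midline triple onto the reference's is recorded for
    pre-alignment of mesh and landmarks.
    """
    glabella = np.asarray(glabella, dtype=float)
    opisthocranion = np.asarray(opisthocranion, dtype=float)
    chord = glabella - opisthocranion
    length = float(np.linalg.norm(chord))
    if length < 1e-9:
        raise ValueError("glabella and opisthocranion coincide")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    axis = chord / length
    n_planes = int(np.floor(length / spacing + 1e-9)) + 1
    offsets = np.arange(n_planes) * spacing

    alignment = None
    if reference_midline is not None:
        if midline_landmarks is None:
            raise ValueError("specimen midline landmarks required for alignment")
        if len(midline_landmarks) < 3:
            raise ValueError("need >=3 midline landmarks for reference alignment")
        alignment, _, _ = opa_align(
            midline_landmarks, reference_midline, allow_scaling=False
        )
    return SlicingFrame(
        axis=axis,
        origin=opisthocranion.copy(),
        offsets=offsets,
        spacing=float(spacing),
        alignment=alignment,
    )


def generate_polylines(mesh: TriMesh, frame: SlicingFrame) -> list[PlaneSection]:
    """Contour polylines on every plane of the slicing frame.

    Each plane-mesh intersection is chained into polygonal curves; on a
    watertight mesh every curve is closed (first vertex equals last). Open
    chains from non-watertight input are kept but flagged, with a warning.
    Sections are ordered from the opisthocranion toward the glabella.
    """
    tm = mesh.as_trimesh()
    sections: list[PlaneSection] = []
    any_open = False
    for offset in frame.offsets:
        origin, normal = frame.plane(float(offset))
        sec = PlaneSection(offset_mm=float(offset))
        path = tm.section(plane_origin=origin, plane_normal=normal)
        if path is not None:
            for curve in path.discrete:
                pts = np.asarray(curve, dtype=float)
                if len(pts) < 3:
                    continue
                closed = bool(np.linalg.norm(pts[0] - pts[-1]) < 1e-9)
                if not closed:
                    any_open = True
                sec.polylines.append(Polyline(points=pts, closed=closed))
        sections.append(sec)
    if any_open:
        logger.warning("open section chains returned (mesh not watertight?)")
    return sections
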