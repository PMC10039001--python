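"""Region-level shape comparison of the occipital squama.

Group mean shapes over GPA-aligned semilandmark configurations, per-facet
local expansion/contraction maps between template-topology meshes,
arc-length-resampled midsagittal profiles, and the scalar craniometric
measurements (lambda-asteria angle, maximum cranial breadth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh

from .landmarks import InvalidLandmarksError, LandmarkConfiguration
from .meshes import MeshError, TriMesh
from .procrustes import _midsagittal_plane

__all__ = [
    "group_mean_shape",
    "config_to_mesh",
    "local_mesh_diff",
    "midsagittal_profile",
    "lambda_asteria_angle",
    "max_cranial_breadth",
]


def group_mean_shape(
    aligned_configs: list[LandmarkConfiguration],
    labels: dict[str, str],
    group: str,
) -> LandmarkConfiguration:
    """Coordinate-wise mean configuration of one group.

    The inputs must already be GPA-aligned; the mean is taken over the
    specimens whose label equals ``group``.
    """
    members = [c for c in aligned_configs if labels.get(c.specimen_id) == group]
    if not members:
        known = sorted(set(labels.values()))
        raise InvalidLandmarksError(f"no specimens in group {group!r} (known: {known})")
    names = members[0].landmark_names
    for c in members[1:]:
        if c.landmark_names != names:
            raise InvalidLandmarksError("group members must share landmark sets")
    mean = np.mean([c.coords for c in members], axis=0)
    out = members[0].with_coords(mean, specimen_id=f"mean_{group}")
    out.group = group
    return out


def config_to_mesh(
    points: np.ndarray | LandmarkConfiguration,
    triangulation_template: np.ndarray,
) -> TriMesh:
    """Mesh whose vertices are configuration points, faces from a template.

    The same face template applied to homologous configurations yields
    meshes of identical topology, the precondition for local_mesh_diff.
    """
    if isinstance(points, LandmarkConfiguration):
        points = points.coords
    points = np.asarray(points, dtype=float)
    faces = np.asarray(triangulation_template, dtype=np.int64)
    if faces.size and (faces.min() < 0 or faces.max() >= len(points)):
        raise MeshError("triangulation template index out of range")
    return TriMesh(points, faces, validate=True)


def local_mesh_diff(
    mesh_a: TriMesh, mesh_b: TriMesh
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-facet signed relative area change of b with respect to a.

    v_f = (area_b_f - area_a_f) / area_a_f: positive where b is locally
    expanded relative to a, negative where contracted. Returns the values
    and summary statistics (mean, sd, min, max). Requires identical
    topology (same face list).
    """
    if mesh_a.faces.shape != mesh_b.faces.shape or not np.array_equal(
        mesh_a.faces, mesh_b.faces
    ):
        raise MeshError("meshes must share an identical face list")
    area_a = mesh_a.face_areas
    area_b = mesh_b.face_areas
    v = (area_b - area_a) / area_a
    summary = {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
    }
    return v, summary


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Arc-length resampling of an ordered 3D polyline to n equidistant points."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, points[:, d])
    return out


def midsagittal_profile(
    mesh: TriMesh,
    start_point: np.ndarray,
    end_point: np.ndarray,
    plane_origin: np.ndarray | None = None,
    plane_normal: np.ndarray | None = None,
    n_points: int = 30,
) -> np.ndarray:
    """Midsagittal profile polyline between two anatomical points.

    The mesh is intersected with the midsagittal plane (default: the plane
    through start and end points and containing their connecting chord,
    computed from the supplied origin/normal); the section curve nearest
    to both points is trimmed between them and resampled to ``n_points``
    equidistant points, the first at the start landmark (e.g. lambda) and
    the last at the end point.
    """
    start = np.asarray(start_point, dtype=float)
    end = np.asarray(end_point, dtype=float)
    if plane_origin is None or plane_normal is None:
        raise ValueError("plane origin and normal are required")
    plane_origin = np.asarray(plane_origin, dtype=float)
    plane_normal = np.asarray(plane_normal, dtype=float)
    plane_normal = plane_normal / np.linalg.norm(plane_normal)

    section = mesh.as_trimesh().section(
        plane_origin=plane_origin, plane_normal=plane_normal
    )
    if section is None:
        raise MeshError("midsagittal plane does not intersect the mesh")
    curves = [np.asarray(c) for c in section.discrete]

    def dist_to(curve: np.ndarray, p: np.ndarray) -> float:
        return float(np.linalg.norm(curve - p, axis=1).min())

    best = min(curves, key=lambda c: dist_to(c, start) + dist_to(c, end))
    tol = 0.05 * np.linalg.norm(start - end)
    if dist_to(best, start) > tol or dist_to(best, end) > tol:
        raise MeshError("start/end landmarks do not lie on the section curve")

    closed = np.allclose(best[0], best[-1], atol=1e-9)
    pts = best[:-1] if closed else best
    i0 = int(np.linalg.norm(pts - start, axis=1).argmin())
    i1 = int(np.linalg.norm(pts - end, axis=1).argmin())
    if closed:
        # two candidate arcs around the loop; take the shorter
        n = len(pts)
        fwd_idx = [(i0 + k) % n for k in range((i1 - i0) % n + 1)]
        bwd_idx = [(i0 - k) % n for k in range((i0 - i1) % n + 1)]
        arc_fwd = pts[fwd_idx]
        arc_bwd = pts[bwd_idx]
        len_f = np.linalg.norm(np.diff(arc_fwd, axis=0), axis=1).sum()
        len_b = np.linalg.norm(np.diff(arc_bwd, axis=0), axis=1).sum()
        arc = arc_fwd if len_f <= len_b else arc_bwd
    else:
        lo, hi = min(i0, i1), max(i0, i1)
        arc = pts[lo : hi + 1]
        if i0 > i1:
            arc = arc[::-1]
    if len(arc) < 2:
        raise MeshError("degenerate profile between start and end")
    return _resample_polyline(arc, n_points)


def midsagittal_plane_from_config(
    config: LandmarkConfiguration, midline_names: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(origin, unit normal) of the least-squares midline plane."""
    names = midline_names or (
        list(config.pairing.midline) if config.pairing else None
    )
    if not names or len(names) < 3:
        raise InvalidLandmarksError("need >=3 midline landmarks for the plane")
    pts = np.array([config.get(n) for n in names])
    return _midsagittal_plane(pts)


def lambda_asteria_angle(config: LandmarkConfiguration) -> float:
    """Angle (degrees) at lambda between the two lambda-to-asterion vectors."""
    for name in ("lambda", "asterion_L", "asterion_R"):
        if name not in config.landmark_names or config.missing_mask[
            config.index_of(name)
        ]:
            raise InvalidLandmarksError(f"landmark {name!r} missing")
    apex = config.get("lambda")
    v1 = config.get("asterion_L") - apex
    v2 = config.get("asterion_R") - apex
    cosang = np.clip(
        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0
    )
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class BreadthResult:
    breadth_mm: float
    point_left: np.ndarray
    point_right: np.ndarray


def max_cranial_breadth(
    mesh: TriMesh,
    plane_origin: np.ndarray,
    plane_normal: np.ndarray,
) -> BreadthResult:
    """Maximum cranial breadth perpendicular to the midsagittal plane.

    The breadth is the largest difference in signed distance from the
    plane over all vertex pairs (equivalently max minus min signed
    distance); the two achieving vertices locate the measurement.
    """
    if len(mesh.vertices) == 0:
        raise MeshError("empty mesh")
    normal = np.asarray(plane_normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    d = (mesh.vertices - np.asarray(plane_origin, dtype=float)) @ normal
    i_max, i_min = int(d.argmax()), int(d.argmin())
    return BreadthResult(
        breadth_mm=float(d[i_max] - d[i_min]),
        point_left=mesh.vertices[i_max].copy(),
        point_right=mesh.vertices[i_min].copy(),
    )
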