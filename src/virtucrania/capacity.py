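"""Cranial-capacity estimation via TPS warping of a reference endocast.

The capacity of a specimen whose endocranial cavity cannot be segmented
(e.g. a fossil still in situ) is estimated by (1) establishing point
correspondence between reference and target crania through fixed
landmarks plus surface semilandmarks (projected and slid to minimise TPS
bending energy), (2) warping the reference's endocast mesh through the
TPS that maps the reference configuration onto the target's, and (3)
integrating the warped mesh volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh as _trimesh

from .landmarks import InvalidLandmarksError, LandmarkConfiguration
from .meshes import TriMesh, mesh_volume
from .tps import tps_fit, tps_warp

logger = logging.getLogger(__name__)

__all__ = [
    "SemilandmarkSet",
    "project_surface_semilandmarks",
    "slide_semilandmarks",
    "estimate_capacity",
]


@dataclass
class SemilandmarkSet:
    """Fixed landmarks plus surface semilandmarks bound to one specimen."""

    fixed: LandmarkConfiguration
    surface_semis: np.ndarray  # (S, 3), on the host mesh surface
    provenance: str = "projected"  # "projected" | "slid"

    def __post_init__(self) -> None:
        self.surface_semis = np.asarray(self.surface_semis, dtype=float)
        if self.surface_semis.ndim != 2 or self.surface_semis.shape[1] != 3:
            raise InvalidLandmarksError("surface_semis must be (S, 3)")

    @property
    def all_points(self) -> np.ndarray:
        return np.vstack([self.fixed.coords, self.surface_semis])

    def check_on_mesh(self, mesh: TriMesh, tol: float = 1e-6) -> bool:
        closest, dist, _ = _trimesh.proximity.closest_point_naive(
            mesh.as_trimesh(), self.surface_semis
        )
        return bool(np.max(dist) < tol)


def _project_to_mesh(points: np.ndarray, mesh: TriMesh) -> np.ndarray:
    closest, dist, _ = _trimesh.proximity.closest_point_naive(mesh.as_trimesh(), points)
    closest = np.asarray(closest)
    if not np.isfinite(closest).all():
        raise InvalidLandmarksError("non-finite surface projection (empty mesh?)")
    return closest


def project_surface_semilandmarks(
    template: SemilandmarkSet,
    template_mesh: TriMesh,
    target_mesh: TriMesh,
    target_fixed: LandmarkConfiguration,
) -> SemilandmarkSet:
    """Transfer template surface semilandmarks onto a target specimen.

    A TPS fitted on the fixed landmarks (template -> target) carries each
    template semilandmark into the target's frame; each carried point is
    then projected to the nearest point of the target surface.
    """
    if template.fixed.landmark_names != target_fixed.landmark_names:
        raise InvalidLandmarksError("fixed landmarks must be homologous")
    model = tps_fit(template.fixed.coords, target_fixed.coords)
    mapped = tps_warp(model, template.surface_semis)
    projected = _project_to_mesh(mapped, target_mesh)
    return SemilandmarkSet(
        fixed=target_fixed.copy(),
        surface_semis=projected,
        provenance="projected",
    )


def _bending_energy_matrix(source_points: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of a source configuration (kernel U(r)=r)."""
    n = len(source_points)
    diff = source_points[:, None, :] - source_points[None, :, :]
    K = np.sqrt((diff**2).sum(axis=2))
    P = np.hstack([np.ones((n, 1)), source_points])
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = K
    L[:n, n:] = P
    L[n:, :n] = P.T
    Linv = np.linalg.pinv(L)
    return Linv[:n, :n]


def _tangent_bases(mesh: TriMesh, points: np.ndarray) -> np.ndarray:
    """(S, 3, 2) orthonormal tangent bases at the nearest surface points."""
    tm = mesh.as_trimesh()
    _, _, face_ids = _trimesh.proximity.closest_point_naive(tm, points)
    normals = np.asarray(tm.face_normals)[face_ids]
    bases = np.empty((len(points), 3, 2))
    for i, nrm in enumerate(normals):
        ref = np.array([0.0, 0.0, 1.0])
        if abs(nrm @ ref) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        e1 = np.cross(nrm, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(nrm, e1)
        bases[i, :, 0] = e1
        bases[i, :, 1] = e2
    return bases


def bending_energy(reference_points: np.ndarray, target_points: np.ndarray) -> float:
    """TPS bending energy of the map reference -> target.

    With the 3D kernel U(r) = r the quadratic form trace(T.T B T) is
    negative semidefinite, so the energy is its negation (clamped at zero
    against rounding). The sliding solve is unaffected: the stationary
    point of the quadratic is the same under either sign.
    """
    B = _bending_energy_matrix(reference_points)
    return float(max(-np.trace(target_points.T @ B @ target_points), 0.0))


def slide_semilandmarks(
    sset: SemilandmarkSet,
    host_mesh: TriMesh,
    reference: SemilandmarkSet,
    iterations: int = 3,
) -> SemilandmarkSet:
    """Slide semilandmarks along the surface to minimise bending energy.

    Each iteration solves the linearised problem: semilandmarks move
    within their local tangent planes to minimise the TPS bending energy
    of the reference-to-target map (fixed landmarks pinned), then are
    re-projected onto the host surface. The energy is non-increasing
    across accepted iterations; two consecutive increases stop the
    procedure, returning the best configuration seen.
    """
    if len(reference.surface_semis) != len(sset.surface_semis):
        raise InvalidLandmarksError("semilandmark counts must match the reference")
    n_fixed = len(sset.fixed)
    S = len(sset.surface_semis)
    Q = reference.all_points  # TPS source
    B = _bending_energy_matrix(Q)
    n = n_fixed + S

    current = sset.surface_semis.copy()
    best = current.copy()
    best_energy = bending_energy(Q, np.vstack([sset.fixed.coords, current]))
    increases = 0

    for _ in range(iterations):
        T0 = np.vstack([sset.fixed.coords, current])
        U = _tangent_bases(host_mesh, current)  # (S, 3, 2)
        # x = vec([Tx; Ty; Tz]) (3n); Delta = M a, a in R^{2S}
        M = np.zeros((3 * n, 2 * S))
        for i in range(S):
            row = n_fixed + i
            for d in range(3):
                M[d * n + row, 2 * i : 2 * i + 2] = U[i, d, :]
        B3 = np.kron(np.eye(3), B)
        x0 = T0.T.ravel()  # [all x; all y; all z]
        A = M.T @ B3 @ M
        b = M.T @ B3 @ x0
        a, *_ = np.linalg.lstsq(A, -b, rcond=None)
        slid = current + (U @ a.reshape(S, 2)[:, :, None]).squeeze(-1)
        slid = _project_to_mesh(slid, host_mesh)
        energy = bending_energy(Q, np.vstack([sset.fixed.coords, slid]))
        if energy < best_energy:
            best_energy = energy
            best = slid.copy()
            increases = 0
        else:
            increases += 1
            if increases >= 2:
                logger.warning("sliding diverged; returning best configuration")
                break
        current = slid
    return SemilandmarkSet(
        fixed=sset.fixed.copy(), surface_semis=best, provenance="slid"
    )


def estimate_capacity(
    reference_endocast: TriMesh,
    reference_set: SemilandmarkSet,
    target_set: SemilandmarkSet,
    use_semis: bool = True,
) -> float:
    """Cranial capacity (cc) of the target via endocast warping.

    A TPS fitted on the reference's fixed landmarks plus surface
    semilandmarks (or fixed only, with ``use_semis=False``) onto the
    target's carries every vertex of the reference endocast into the
    target's frame; the warped mesh's enclosed volume is the capacity.
    """
    if reference_set.fixed.landmark_names != target_set.fixed.landmark_names:
        raise InvalidLandmarksError("fixed landmark sets must be homologous")
    if use_semis:
        if len(reference_set.surface_semis) != len(target_set.surface_semis):
            raise InvalidLandmarksError("semilandmark counts must match")
        src = reference_set.all_points
        dst = target_set.all_points
    else:
        src = reference_set.fixed.coords
        dst = target_set.fixed.coords
    model = tps_fit(src, dst)
    warped = reference_endocast.with_vertices(
        tps_warp(model, reference_endocast.vertices)
    )
    return mesh_volume(warped)
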