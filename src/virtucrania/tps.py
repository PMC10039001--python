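"""3D thin-plate-spline interpolation and missing-landmark estimation.

The TPS maps one landmark configuration exactly onto another and extends
smoothly in between; it is the workhorse for warping meshes (endocasts,
deformation maps) and for estimating landmarks hidden on a fossil from a
complete reference specimen. The radial kernel is U(r) = r, the standard
3D spline kernel of common geometric-morphometric software.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import InvalidLandmarksError, LandmarkConfiguration

__all__ = ["TPSModel", "tps_fit", "tps_warp", "estimate_missing_landmarks"]

KERNEL_3D = "U(r)=r"


class SingularTPSError(ValueError):
    """TPS linear system is singular (e.g. duplicate source landmarks)."""


@dataclass(frozen=True)
class TPSModel:
    """Fitted thin-plate spline from ``source_landmarks`` onto a target.

    ``affine`` is a 3x4 matrix acting on homogeneous [1, x, y, z];
    ``weights`` are the N non-affine coefficients per output dimension.
    The side conditions (weights orthogonal to constants and to the source
    coordinates) hold by construction of the bordered linear system.
    """

    source_landmarks: np.ndarray  # (N, 3)
    affine: np.ndarray  # (3, 4)
    weights: np.ndarray  # (N, 3)
    kernel: str = KERNEL_3D

    @property
    def bending_energy(self) -> float:
        """Non-affine deformation energy; zero iff the map is affine.

        With the 3D kernel U(r) = r the quadratic form trace(W.T K W) is
        negative semidefinite on the admissible weights (P.T W = 0), so
        the energy is its negation, clamped at zero against rounding.
        """
        K = _kernel_matrix(self.source_landmarks, self.source_landmarks)
        return float(max(-np.trace(self.weights.T @ K @ self.weights), 0.0))

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return tps_warp(self, points)


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def tps_fit(
    source: LandmarkConfiguration | np.ndarray,
    target: LandmarkConfiguration | np.ndarray,
) -> TPSModel:
    """Fit a 3D TPS mapping source landmarks exactly onto target landmarks.

    Requires at least 5 non-coplanar correspondences and no duplicate
    source points (duplicates make the bordered system singular and are
    reported by name/index).
    """
    names: list[str] | None = None
    if isinstance(source, LandmarkConfiguration):
        names = source.landmark_names
        src = source.coords[~source.missing_mask]
        names = [n for n, m in zip(names, source.missing_mask) if not m]
    else:
        src = np.asarray(source, dtype=float)
    if isinstance(target, LandmarkConfiguration):
        tgt = target.coords[~target.missing_mask]
    else:
        tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise InvalidLandmarksError("source/target must be matching (N, 3) arrays")
    n = src.shape[0]
    if n < 5:
        raise InvalidLandmarksError(f"TPS needs >=5 landmarks, got {n}")
    # duplicate detection
    d = _kernel_matrix(src, src)
    dup = np.argwhere(np.triu(d < 1e-9, k=1))
    if dup.size:
        i, j = dup[0]
        label = (
            f"{names[i]!r} and {names[j]!r}" if names else f"indices {i} and {j}"
        )
        raise SingularTPSError(f"duplicate source landmarks: {label}")
    if np.linalg.matrix_rank(src - src.mean(axis=0), tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise InvalidLandmarksError("source landmarks are coplanar; TPS underdetermined")

    P = np.hstack([np.ones((n, 1)), src])  # (n, 4)
    L = np.zeros((n + 4, n + 4))
    L[:n, :n] = d
    L[:n, n:] = P
    L[n:, :n] = P.T
    rhs = np.zeros((n + 4, 3))
    rhs[:n] = tgt
    try:
        sol = np.linalg.solve(L, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularTPSError(f"TPS system singular: {exc}") from exc
    weights = sol[:n]
    affine = sol[n:].T  # (3, 4) acting on [1, x, y, z]
    return TPSModel(source_landmarks=src.copy(), affine=affine, weights=weights)


def tps_warp(model: TPSModel, points: np.ndarray) -> np.ndarray:
    """Map arbitrary 3D points through a fitted TPS."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    U = _kernel_matrix(pts, model.source_landmarks)  # (M, N)
    hom = np.hstack([np.ones((pts.shape[0], 1)), pts])  # (M, 4)
    return hom @ model.affine.T + U @ model.weights


def estimate_missing_landmarks(
    partial_target: LandmarkConfiguration,
    full_reference: LandmarkConfiguration,
) -> LandmarkConfiguration:
    """Estimate a specimen's missing landmarks from a complete reference.

    The reference is Procrustes-registered (shape and size) onto the
    target over the shared non-missing landmarks; a TPS is fitted from the
    registered reference to the target over those landmarks; the
    reference's positions for the missing landmarks are then mapped
    through the TPS. The returned configuration is complete, with the
    estimated points flagged in ``estimated_mask``.
    """
    from .procrustes import opa_align

    if full_reference.missing_mask.any():
        raise InvalidLandmarksError("reference must be complete")
    missing_names = [
        n
        for n, m in zip(partial_target.landmark_names, partial_target.missing_mask)
        if m
    ]
    if not missing_names:
        return partial_target.copy()
    for n in missing_names:
        if n not in full_reference.landmark_names:
            raise InvalidLandmarksError(f"reference lacks missing landmark {n!r}")
    shared_names = [
        n
        for n, m in zip(partial_target.landmark_names, partial_target.missing_mask)
        if not m and n in full_reference.landmark_names
    ]
    if len(shared_names) < 5:
        raise InvalidLandmarksError(
            f"need >=5 shared landmarks to estimate, got {len(shared_names)}"
        )
    ref_shared = full_reference.subset(shared_names)
    tgt_shared = partial_target.subset(shared_names)
    transform, ref_aligned, _ = opa_align(ref_shared, tgt_shared, allow_scaling=True)
    model = tps_fit(ref_aligned.coords, tgt_shared.coords)

    # the same similarity transform carries the reference's positions for
    # the missing landmarks into the target frame before the TPS mapping
    ref_missing = np.array([full_reference.get(n) for n in missing_names])
    ref_missing_aligned = transform.apply(ref_missing)
    estimated = tps_warp(model, ref_missing_aligned)

    coords = partial_target.coords.copy()
    est_mask = partial_target.estimated_mask.copy()
    for name, pos in zip(missing_names, estimated):
        i = partial_target.index_of(name)
        coords[i] = pos
        est_mask[i] = True
    return LandmarkConfiguration(
        specimen_id=partial_target.specimen_id,
        landmark_names=list(partial_target.landmark_names),
        coords=coords,
        missing_mask=np.zeros(len(partial_target), dtype=bool),
        pairing=partial_target.pairing,
        estimated_mask=est_mask,
        group=partial_target.group,
    )
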