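"""Ordinary and generalized Procrustes superimposition, and symmetrisation.

Superimposition removes location, orientation and (optionally) size from
landmark configurations so that only shape remains. Reflections are never
permitted: anatomical chirality is preserved (rotation determinant +1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import InvalidLandmarksError, LandmarkConfiguration, centroid_size

__all__ = ["SimilarityTransform", "opa_align", "gpa", "symmetrise"]


class DegenerateGeometryError(ValueError):
    """Landmark geometry too degenerate for the requested operation."""


@dataclass(frozen=True)
class SimilarityTransform:
    """x -> scale * rotation @ x + translation (mm)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    scale: float = 1.0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must have determinant +1 (no reflection)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        Rinv = self.rotation.T
        return SimilarityTransform(
            rotation=Rinv,
            translation=-(Rinv @ self.translation) / self.scale,
            scale=1.0 / self.scale,
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
            scale=self.scale * other.scale,
        )

    @staticmethod
    def identity() -> "SimilarityTransform":
        return SimilarityTransform(np.eye(3), np.zeros(3), 1.0)


def _kabsch(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation mapping centred source onto centred target."""
    H = source.T @ target
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def opa_align(
    source: LandmarkConfiguration,
    target: LandmarkConfiguration,
    allow_scaling: bool = True,
) -> tuple[SimilarityTransform, LandmarkConfiguration, float]:
    """Ordinary Procrustes analysis: superimpose ``source`` onto ``target``.

    The least-squares optimal rotation, translation and (optionally) scale
    are estimated over the landmarks non-missing in both configurations;
    the transform is then applied to every source landmark. Returns the
    transform, the aligned source and the RMS residual (mm) over the
    common landmarks. Reflections are never allowed.
    """
    if source.landmark_names != target.landmark_names:
        raise InvalidLandmarksError("OPA requires identical landmark names/order")
    common = ~(source.missing_mask | target.missing_mask)
    if common.sum() < 3:
        raise InvalidLandmarksError(
            f"OPA needs >=3 common landmarks, got {int(common.sum())}"
        )
    X = source.coords[common]
    Y = target.coords[common]
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    # collinearity check: rank of the centred common points
    if np.linalg.matrix_rank(Xc, tol=1e-9 * max(1.0, np.abs(Xc).max())) < 2:
        raise DegenerateGeometryError("common landmarks are collinear")
    R = _kabsch(Xc, Yc)
    if allow_scaling:
        num = np.trace(R @ Xc.T @ Yc)
        den = (Xc**2).sum()
        s = float(num / den)
        if s <= 0:
            raise DegenerateGeometryError("non-positive optimal scale")
    else:
        s = 1.0
    t = my - s * R @ mx
    transform = SimilarityTransform(rotation=R, translation=t, scale=s)
    aligned_coords = transform.apply(source.coords)
    aligned = source.with_coords(aligned_coords)
    residual = float(np.sqrt(((transform.apply(X) - Y) ** 2).sum(axis=1).mean()))
    return transform, aligned, residual


def gpa(
    configs: list[LandmarkConfiguration],
    with_scaling: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[LandmarkConfiguration, list[LandmarkConfiguration], np.ndarray]:
    """Generalized Procrustes analysis over complete configurations.

    Iteratively superimposes all configurations onto an evolving consensus
    (initialised deterministically from the first specimen) until the
    consensus moves by less than ``tol`` between iterations. With scaling,
    every configuration and the consensus are kept at unit centroid size.

    Returns (consensus, aligned configurations, per-specimen Procrustes
    distances to the consensus).
    """
    if len(configs) < 2:
        raise InvalidLandmarksError("GPA needs at least 2 configurations")
    names = configs[0].landmark_names
    for c in configs:
        if c.landmark_names != names:
            raise InvalidLandmarksError("GPA requires homologous landmark sets")
        if c.missing_mask.any():
            raise InvalidLandmarksError(
                f"GPA requires complete configurations; {c.specimen_id} has "
                f"missing landmarks (estimate them first)"
            )

    def normalise(pts: np.ndarray) -> np.ndarray:
        pts = pts - pts.mean(axis=0)
        if with_scaling:
            pts = pts / np.sqrt((pts**2).sum())
        return pts

    shapes = [normalise(c.coords.copy()) for c in configs]
    consensus = shapes[0].copy()
    for _ in range(max_iter):
        for i, sh in enumerate(shapes):
            R = _kabsch(sh, consensus)
            shapes[i] = sh @ R.T
        new_consensus = normalise(np.mean(shapes, axis=0))
        # align new consensus onto old for a stable convergence criterion
        R = _kabsch(new_consensus, consensus)
        new_consensus = new_consensus @ R.T
        change = np.sqrt(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if change < tol:
            break
    aligned = [
        c.with_coords(sh) for c, sh in zip(configs, shapes)
    ]
    consensus_config = configs[0].with_coords(consensus, specimen_id="consensus")
    from .landmarks import procrustes_distance

    distances = np.array(
        [procrustes_distance(a, consensus_config) for a in aligned]
    )
    return consensus_config, aligned, distances


def _midsagittal_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (point_on_plane, unit normal)."""
    centre = points.mean(axis=0)
    _, _, Vt = np.linalg.svd(points - centre)
    normal = Vt[-1]
    return centre, normal / np.linalg.norm(normal)


def _reflect(coords: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    d = (coords - origin) @ normal
    return coords - 2.0 * np.outer(d, normal)


def symmetrise(
    config: LandmarkConfiguration,
    tol: float = 1e-12,
    max_iter: int = 20,
) -> LandmarkConfiguration:
    """Bilaterally symmetrise a configuration about its midsagittal plane.

    The configuration is reflected across the least-squares plane through
    its midline landmarks, left/right labels are swapped, the relabelled
    reflection is rigidly registered back onto the original, and the two
    are averaged. The step is iterated to its fixed point so the output is
    exactly symmetric (mirrored pairs equidistant from the midplane) and
    the operation is idempotent.
    """
    if config.pairing is None:
        raise InvalidLandmarksError("symmetrise requires a pairing table")
    midline = list(config.pairing.midline)
    if len(midline) < 3:
        raise InvalidLandmarksError(
            f"symmetrise needs >=3 midline landmarks, got {len(midline)}"
        )
    if config.missing_mask.any():
        raise InvalidLandmarksError("symmetrise requires a complete configuration")

    names = config.landmark_names
    # permutation that swaps each bilateral pair, identity on midline
    perm = np.arange(len(names))
    for left, right in config.pairing.pairs:
        i, j = names.index(left), names.index(right)
        perm[i], perm[j] = j, i

    mid_idx = [names.index(m) for m in midline]
    current = config.coords.copy()
    for _ in range(max_iter):
        origin, normal = _midsagittal_plane(current[mid_idx])
        reflected = _reflect(current, origin, normal)[perm]
        ref_cfg = config.with_coords(reflected)
        cur_cfg = config.with_coords(current)
        _, aligned, _ = opa_align(ref_cfg, cur_cfg, allow_scaling=False)
        new = 0.5 * (current + aligned.coords)
        change = np.abs(new - current).max()
        current = new
        if change < tol:
            break
    return config.with_coords(current)
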