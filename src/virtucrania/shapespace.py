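"""Comparative shape space: GPA + tangent-space PCA + projection + PC maps.

The comparative sample is superimposed by generalized Procrustes analysis
and orthogonally projected onto the tangent space at the consensus (the
component of each unit-size, aligned shape along the consensus direction
is removed). The principal components are an eigendecomposition of the
covariance matrix of the tangent coordinates. Query specimens (e.g.
virtual reconstructions) are registered and projected through exactly the
same path, out-of-sample: they never alter the space. The tangent
construction makes the key identities exact: training scores have zero
mean, re-projecting a training specimen recovers its stored scores, and
the consensus itself projects to the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import InvalidLandmarksError, LandmarkConfiguration
from .meshes import TriMesh
from .procrustes import _kabsch, gpa
from .tps import tps_fit, tps_warp

__all__ = ["ShapeSpace", "build_shape_space", "project_specimen", "pc_extreme_maps"]


@dataclass
class ShapeSpace:
    """GPA consensus + PCA basis over a comparative sample."""

    mean_shape: LandmarkConfiguration  # unit centroid size, zero centroid
    centre: np.ndarray  # (3N,) mean tangent coordinate (0 up to rounding)
    eigenvectors: np.ndarray  # (3N, K), orthogonal to the consensus direction
    eigenvalues: np.ndarray  # (K,)
    variance_fraction: np.ndarray  # (K,)
    scores: np.ndarray  # (n, K) training scores
    specimen_ids: list[str]
    group_labels: dict[str, str]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _normalise(coords: np.ndarray) -> np.ndarray:
    """Zero centroid, unit centroid size."""
    c = coords - coords.mean(axis=0)
    return c / np.sqrt((c**2).sum())


def _tangent_coords(coords: np.ndarray, mean_flat: np.ndarray) -> np.ndarray:
    """Register a configuration and project into the tangent space.

    Centre, scale to unit centroid size, rotate optimally onto the
    consensus, then remove the component along the consensus direction.
    """
    x = _normalise(coords)
    mean_pts = mean_flat.reshape(-1, 3)
    R = _kabsch(x, mean_pts)
    flat = (x @ R.T).ravel()
    return flat - (flat @ mean_flat) * mean_flat


def build_shape_space(
    configs: list[LandmarkConfiguration],
    group_labels: dict[str, str] | None = None,
) -> ShapeSpace:
    """Build the shape space of a comparative sample.

    GPA (with scaling) yields the unit-size consensus; every specimen is
    registered onto it and projected orthogonally into the tangent space;
    the PCA is an eigendecomposition of the covariance matrix of the
    tangent coordinates. Components are ordered by decreasing eigenvalue,
    with each eigenvector's sign fixed so its largest-magnitude loading is
    positive.
    """
    if len(configs) < 3:
        raise InvalidLandmarksError("shape space needs >= 3 specimens")
    _, aligned, _ = gpa(configs, with_scaling=True)
    # consensus direction = normalised mean of the aligned, unit-size shapes
    mean_flat = _normalise(np.mean([a.coords for a in aligned], axis=0)).ravel()
    Y = np.stack([_tangent_coords(c.coords, mean_flat) for c in configs])
    centre = Y.mean(axis=0)  # zero up to rounding, by the tangent construction
    Yc = Y - centre
    n = len(configs)
    _, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    keep = eigenvalues > 1e-12 * max(eigenvalues.max(), 1e-30)
    eigenvalues = eigenvalues[keep]
    V = Vt[keep].T  # (3N, K)
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    scores = Yc @ V
    variance_fraction = eigenvalues / eigenvalues.sum()
    mean_shape = configs[0].with_coords(
        mean_flat.reshape(-1, 3), specimen_id="consensus"
    )
    mean_shape.group = None
    return ShapeSpace(
        mean_shape=mean_shape,
        centre=centre,
        eigenvectors=V,
        eigenvalues=eigenvalues,
        variance_fraction=variance_fraction,
        scores=scores,
        specimen_ids=[c.specimen_id for c in configs],
        group_labels=dict(
            group_labels or {c.specimen_id: (c.group or "") for c in configs}
        ),
    )


def project_specimen(space: ShapeSpace, config: LandmarkConfiguration) -> np.ndarray:
    """Out-of-sample PC scores of a specimen.

    The specimen is registered onto the consensus (translation, unit-size
    scaling, optimal rotation), projected into the tangent space and
    scored against the eigenvectors — the identical path used for the
    training sample. The space itself is not updated.
    """
    if config.landmark_names != space.mean_shape.landmark_names:
        raise InvalidLandmarksError(
            "query landmarks must match the shape space's landmark set"
        )
    if config.missing_mask.any():
        raise InvalidLandmarksError("projection requires a complete configuration")
    y = _tangent_coords(config.coords, space.mean_shape.coords.ravel())
    return (y - space.centre) @ space.eigenvectors


@dataclass
class PCExtremeMaps:
    """Meshes warped to the +/- extremes of one PC, with local area change."""

    mesh_mean: TriMesh
    mesh_minus: TriMesh
    mesh_plus: TriMesh
    diff_minus: np.ndarray  # per-facet relative area change vs the mean mesh
    diff_plus: np.ndarray


def pc_extreme_maps(
    space: ShapeSpace,
    pc_index: int,
    k_sd: float,
    template_mesh: TriMesh,
    template_config: LandmarkConfiguration,
    scale_mm: float | None = None,
) -> PCExtremeMaps:
    """Morphology at the +/- k_sd extremes of one principal component.

    Landmark targets are consensus +/- k_sd * sqrt(eigenvalue) *
    eigenvector, rendered at ``scale_mm`` centroid size (default: the
    template's own size). The template mesh is TPS-warped to the mean and
    to both extremes; per-facet signed relative area change of each
    extreme vs the mean mesh quantifies local expansion (+) and
    contraction (-).
    """
    from .landmarks import centroid_size
    from .occipital import local_mesh_diff

    if not 0 <= pc_index < space.n_components:
        raise IndexError(
            f"pc_index {pc_index} out of range (space has {space.n_components})"
        )
    if template_config.landmark_names != space.mean_shape.landmark_names:
        raise InvalidLandmarksError("template landmarks must match the space")

    cs = scale_mm if scale_mm is not None else centroid_size(template_config)
    mean_flat = space.mean_shape.coords.ravel()
    amplitude = k_sd * np.sqrt(space.eigenvalues[pc_index])
    v = space.eigenvectors[:, pc_index]

    target_mean = mean_flat.reshape(-1, 3) * cs
    target_minus = (mean_flat - amplitude * v).reshape(-1, 3) * cs
    target_plus = (mean_flat + amplitude * v).reshape(-1, 3) * cs

    def warp_to(target: np.ndarray) -> TriMesh:
        model = tps_fit(template_config.coords, target)
        return template_mesh.with_vertices(tps_warp(model, template_mesh.vertices))

    mesh_mean = warp_to(target_mean)
    mesh_minus = warp_to(target_minus)
    mesh_plus = warp_to(target_plus)
    diff_minus, _ = local_mesh_diff(mesh_mean, mesh_minus)
    diff_plus, _ = local_mesh_diff(mesh_mean, mesh_plus)
    return PCExtremeMaps(
        mesh_mean=mesh_mean,
        mesh_minus=mesh_minus,
        mesh_plus=mesh_plus,
        diff_minus=diff_minus,
        diff_plus=diff_plus,
    )
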